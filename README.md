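# ucrna

Expression profiling and RNA loop-loop interaction screening for
transcripts of ultraconserved genomic regions (ucRNAs).

Ultraconserved regions (UCRs) are genomic segments longer than 200 bp
with perfect conservation across the human, mouse and rat genomes; 481
are catalogued, and both strands of many of them are transcribed into
noncoding RNAs. This package implements, as a tested and reusable
pipeline, the computational workflow needed to profile these
transcripts on a custom one-color array and to explore their candidate
functions, for researchers studying noncoding RNA in cancer tissue
cohorts:

- **Strand-aware probe design**: for each UCR, a sense 40-mer probe
  (`uc.N+`) and the antisense reverse complement (`uc.N+A`) — 962
  probesets for the full 481-UCR catalog.
- **Synthetic data with known ground truth**: spot-level array
  simulation (quadruplicate spots per probe plus 3484 blank spots,
  57 tumor / 7 non-tumor cohorts with clinical covariates, planted
  log2 effects), correlated mRNA/miR layers, and hairpin sequence
  pairs with complementary loops.
- **Preprocessing**: blank-spot background subtraction, replicate
  summarization (median of quadruplicates, log2), median-centric
  normalization, low-intensity / minimum-fold-change / 50%-missing
  probe filters; quantile normalization and reference-gene count
  scaling for validation layers.
- **Differential expression**: the SAM-style moderated statistic
  `d_i = (mean_B - mean_A) / (s_i + s0)` with a pooled permutation
  null and Storey–Tibshirani q-values, over seven configurable binary
  clinical contrasts (tumor/normal, Gleason ≥7 / ≤6, pT3/pT2, EPE,
  SVI, race, age ≤60 / ≥61); randomized-block t-test and
  comparative-CT (`2^-ΔΔCt`) fold changes for cell experiments and
  qPCR.
- **Classification**: a nearest shrunken centroid (PAM-style)
  classifier with soft-thresholded standardized centroid differences
  `d'_ik`, cross-validated threshold selection and signature
  extraction, exposed as a scikit-learn-compatible estimator.
- **Correlation scans**: Pearson r with exact t-transform p-values for
  host-gene pair sets (with a distribution summary over the
  (−0.2, 0.2) band), genome-wide per-ucRNA scans, and sense/antisense
  concordance.
- **Loop-loop interaction screen**: dot-bracket structure parsing and
  loop decomposition, a nearest-neighbor intermolecular duplex
  minimum-free-energy dynamic program, and the kissing-loop screen
  that keeps ucRNA:mRNA pairs with duplex ΔG ≤ −10 kcal/mol and more
  than 75% of the shorter loop's bases paired, followed by
  hypergeometric gene-set enrichment of predicted targets.

## Worked example

Simulate a small cohort, preprocess it and run the tumor-vs-normal
class comparison:

```sh
ucrna --seed 3 --out-dir demo simulate --preset tiny --n-effects 5
ucrna --out-dir demo preprocess --spots demo/spots.tsv
ucrna --seed 3 --out-dir demo diffexp --matrix demo/matrix.tsv \
      --annotation demo/annotation.tsv --contrast tumor_vs_normal -b 200
```

which prints:

```
wrote catalog (60 probes), spots, annotation to demo
60 probes retained, 0 dropped
6 probes at q < 0.05; table in demo/diffexp_tumor_vs_normal.tsv
```

The tiny preset plants 5 differential effects among 60 probes
(30 UCRs, 10 tumor vs 4 non-tumor samples); the ranked table lists
per-probe fold change (case over reference, so down-regulation prints
below 1), the moderated d statistic, the pooled-permutation p and the
Storey q. Here 6 probes reach q < 0.05: the 5 planted effects plus one
false call, which is the kind of behavior the q threshold promises on
average. The same library calls are available in Python
(`ucrna.simulate`, `ucrna.preprocess`, `ucrna.differential`, ...), and
the interaction screen is available both as `ucrna interact` /
`ucrna enrich` and as `ucrna.screen_interactions` /
`ucrna.enrich_targets`.

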