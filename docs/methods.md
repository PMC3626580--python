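# Methods

This note documents the models behind each pipeline stage, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic array data

**Catalog.** `gen_ucr_catalog` draws `n_ucr` loci (default 481, the
size of the known UCR catalog) with uniform-random DNA of length
200–780 bp — the >200 bp lower bound is the defining property of a
UCR and is enforced. Class labels (nonexonic / exonic / possibly
exonic, default mix 0.53/0.23/0.24) follow the approximate composition
reported for the real catalog; exonic and possibly-exonic loci get a
synthetic host-gene id. Each locus yields two 40-mer probes: the
central sense 40-mer (`uc.N+`) and its reverse complement (`uc.N+A`).
The central offset is a fixture convention chosen because it is
deterministic and strand-symmetric; it is not a claim about any real
array platform.

**Spot model.** Per spot,

    raw = 2^(b_i + Σ effect·indicator + u_s + ε) + bg

with probe baseline `b_i ~ U(6, 12)` (log2 units), per-sample shift
`u_s ~ N(0, σ_sample)`, per-spot noise `ε ~ N(0, σ_spot)` and additive
background `bg ~ N(μ=50, σ=10)` truncated at 0. Blank spots draw from
the background only. Defaults: σ_sample = 0.3, σ_spot = 0.25,
4 replicates per probe per slide, 3484 blanks, cohort 57 tumor / 7
non-tumor. The log-normal-signal-plus-additive-background form is the
conventional model for one-color spotted arrays; σ defaults were fixed
once as values giving within-cohort coefficients of variation typical
of tissue arrays. Planted effects are `(probe, contrast, log2_effect)`
triples applied to the contrast's case group and recorded in a truth
table, so downstream sensitivity and FDR can be computed without
reading generator internals. Negative noise σ values are rejected;
zero is allowed because the zero-noise limit is a useful degenerate
fixture.

**Clinical covariates.** Tumor samples draw Gleason ≥7 with
probability 0.77, stage pT3–4 0.51, EPE 0.42, SVI 0.18, AA race 0.51,
age from a rounded N(61, 6) clipped to 46–73 — the marginal rates of
the emulated cohort design. Covariates are drawn independently since
only marginals are specified; real cohorts have correlated covariates
(high Gleason co-occurs with high stage), which these fixtures do not
reproduce. Non-tumor samples carry NA in all clinical tumor fields.

**Correlated layers.** A planted (source, target, r) sets
`target = r·standardize(source) + sqrt(1−r²)·z + baseline`, so the
population correlation is exactly r; every unplanted row is
independent of the ucRNA layer. |r| must be < 1.

**Interacting hairpins.** A planted pair is two hairpins (stem ≥ 3 bp,
default 6; loop default 10 nt) whose loop sequences are exact RNA
reverse complements, embedded in unpaired uniform-random flanks; the
designed dot-bracket structures are emitted alongside, so the screen
does not depend on the baseline folder recovering them. Planted loops
are resampled until their full-complement duplex energy under the
bundled parameter table is ≤ −10 kcal/mol: a "planted interaction"
is by definition a thermodynamically stable one under the package's
own energy model. Loops shorter than 6 nt cannot reach −10 kcal/mol
under the table, and the generator raises rather than silently
planting unstable pairs. Decoys are extra mRNA hairpins whose loops
are dinucleotide shuffles (random Eulerian walk over the doublet
graph) of planted loops.

**What passing tests show.** The generators emulate design dimensions,
noise magnitudes and planted signals — not scanner artifacts, spatial
slide effects, dye chemistry, real genomic sequence composition,
correlated clinical covariates, or realistic mRNA secondary
structures. Recovery results on these fixtures demonstrate that the
statistical machinery is correct and calibrated under its own model
assumptions; they do not certify performance on real arrays.

## Preprocessing

Order is fixed: background subtraction → replicate summarization →
median centering → filtering.

- Background: per-slide **median** blank intensity subtracted from
  probe spots (median for robustness; the summary statistic is
  otherwise unspecified in the workflow being emulated), floored at
  ε = 1.0 so log2 is defined.
- Summarization: log2 of the median over non-flagged quadruplicates;
  all-flagged cells are masked "filtered", unprinted cells "missing".
- Median centering: each sample shifted so its median equals the
  global median of per-sample medians (idempotent; "median-centric"
  normalization admits several targets and this one is
  scale-preserving).
- Filtering: cells below `intensity_floor` (default 1.0 on log2, i.e.
  twice the ε floor) are masked; probes whose max/min present ratio is
  below `min_fold_change` (default 1.2) are filtered as uninformative;
  probes with ≥ 50% missing-or-filtered cells are dropped and
  reported. The 50% rule is applied globally, not per contrast — users
  comparing subgroups should re-filter on the subgroup if they need
  the per-contrast reading. Filtering never alters surviving values.
- The mRNA layer uses quantile normalization (columns forced onto the
  row-wise mean of sorted columns, ties averaged) plus log2 as a
  deliberate, simpler substitute for full RMA; the RMA convolution
  background model is out of scope. Count-based validation data are
  scaled so each sample's reference-gene count equals the geometric
  mean of reference counts across samples.

## Differential expression

The moderated statistic is `d_i = (mean_B − mean_A)/(s_i + s0)` with
the pooled two-sample standard error
`s_i = sqrt((1/n_A + 1/n_B)(SS_A + SS_B)/(n_A + n_B − 2))` and fudge
factor `s0 = median(s_i)` by default (a full percentile search adds
little on 962-probe lists and the median keeps rankings monotone for
constant-variance data). Fold changes are `2^(mean_B − mean_A)`,
case over reference, so down-regulation prints below 1.

**Permutation null.** Labels are permuted B times (default 200 in
tests, 1000 for production runs; truncated to the exhaustive set with
a warning when B exceeds the number of distinct assignments). The
permuted |d| of *all* probes are pooled into one null — the SAM-style
choice, which buys resolution `1/(1 + B·m)` at small B — and
`p_i = (1 + #{null |d| ≥ |d_i|})/(1 + pool size)`. Tests are two-sided
throughout.

**q-values.** Storey–Tibshirani: `π0 = min(1, #{p > λ}/((1−λ)m))` at
fixed λ = 0.5 (the spline smoother is unstable on short probe lists),
floored at 1/m so q stays in (0, 1]; step-up
`q_(i) = min_{j≥i} π0·m·p_(j)/j`, capped at 1, order-preserving and
invariant to input order.

**Contrasts.** Seven study contrasts are registered: tumor/normal,
Gleason ≥7 vs ≤6, pT3–4 vs pT2, EPE yes/no, SVI yes/no, AA vs EA,
and age ≤60 vs ≥61 (the dichotomization boundary is fixed at 60/61).
Samples with NA in the contrast field are excluded; each level needs
at least two samples.

Cell-line treatment designs use the randomized-block (paired) t-test;
qPCR uses the comparative-CT fold change `2^(−ΔΔCt)`. Both are exact
closed forms and are checked against hand computation and scipy in the
tests.

**Operating characteristics** are measured, not assumed: the test
suite and acceptance script simulate 20 cohorts at the study
dimensions (962 probes, 57v7, 50 planted effects at |log2FC| ∈
[1, 1.5]) and compute realized FDR at q < 0.05 and sensitivity from
the truth tables. One caveat: because the permutation pool includes
planted-effect probes, null p-values are slightly conservative when
many strong effects are present.

## Nearest shrunken centroid classifier

Standardized centroid differences
`d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s0))` with `m_k² = 1/n_k − 1/n`
(the variance factor of a class centroid minus the overall centroid
under a common within-class variance), soft-thresholded by Δ.
Discriminant: `δ_k(x) = Σ (x_i − x̄'_ik)²/(s_i + s0)² − 2 log π_k`;
ties go to the lexicographically first class with a tie flag. Priors
default to empirical class frequencies; s0 defaults to median(s_i).

Cross-validation is stratified k-fold (default k = 5, compatible with
7 samples in the smaller class; leave-one-out is suggested when k
exceeds the smallest class). Δ is chosen by the one-standard-error
rule — the largest Δ whose overall CV error is within one SE (across
folds) of the minimum — which favors smaller signatures; users who
want a fixed signature size can scan the reported per-Δ signature
sizes instead. Signature size is a nonincreasing step function of Δ,
and Δ = 0 reduces exactly to a standardized nearest-centroid
classifier; both properties are asserted in tests against an
independent oracle.

## Correlation analyses

Pearson r on pairwise-complete shared samples (n_used recorded;
pairs with fewer than 3 complete samples are skipped and reported),
with two-sided p from `t = r·sqrt((n−2)/(1−r²))`. The pair-distribution
summary reports mean, SD and the fraction of pairs inside (−0.2, 0.2);
under independence at n = 57 that fraction has an exact null value via
the t transform, and the tests check the simulated fixtures against
it. Genome-wide scans sort by |r| and always retain raw p;
Benjamini–Hochberg adjustment is available but off by default to
mirror raw-p reporting conventions for exploratory scans. The
host-gene pairing table is an explicit input; no genome annotation
lookup is performed. The default cohort filter for pair analyses is
the caller's choice of samples — pass the tumor subset to reproduce a
tumors-only analysis.

## Loop-loop interaction screen

**Structures.** Dot-bracket structures are validated for balanced
nesting and canonical chemistry (Watson–Crick + GU). The loop
decomposition is a partition: every position belongs to a helix or to
exactly one loop element (hairpin, bulge, internal, multibranch,
exterior). The bundled folder is a Nussinov maximum-pairing DP with
minimum hairpin size 3, GU allowed and a deterministic traceback
(ties prefer the smaller opening index); it is a zero-dependency
baseline, not a minimum-free-energy predictor, and externally
predicted structures (e.g. RNAfold output in Vienna format) can be
supplied instead.

**Duplex energy.** Intermolecular, antiparallel, non-crossing pairings
scored as initiation (+4.09 kcal/mol) + nearest-neighbor stacks +
size-dependent interior-loop/bulge penalties with total unpaired size
capped at 4; intramolecular pairs are forbidden (a single kissing
duplex per pair; multi-site interactions are out of scope). The
parameter table (`src/ucrna/data/nn_params.tsv`) is a documented
plain-text file and the single source of truth for both the DP and the
test oracle: Watson–Crick stacks follow the standard Turner-2004
literature values; GU stacks are curated approximations obeying
nearest-neighbor strand symmetry. Absolute energies therefore depend
on this table and are not claimed to match ViennaRNA. The DP is
checked for exact agreement with exhaustive enumeration on hundreds of
short random instances.

**Screen.** For each ucRNA:mRNA pair, hairpin loops of at least 4 nt
are extracted from both structures (other loop types can be requested)
and every loop×loop duplex is scored; the best duplex is the lowest-ΔG
one, ties broken by larger bond fraction, then loop order. A pair
passes iff ΔG ≤ −10 kcal/mol **and** bond fraction > 0.75. Two
interpretation choices are deliberate: the energy threshold is read as
a *stability* cutoff (more negative than −10), since keeping only
weaker-than-−10 duplexes would contradict the screen's intent; and the
bond-fraction denominator is the shorter loop's length (an alternative
union denominator is exposed as an option). Both inequalities'
directions and the strictness of ">75%" are pinned by tests. Output
order is (ucrna_id, mrna_id), invariant to input ordering.

**Enrichment.** Upper-tail hypergeometric p per gene set
(`P[X ≥ overlap]` with population = universe, successes = set ∩
universe, draws = targets), Benjamini–Hochberg across sets.

## Numerical conventions and degenerate inputs

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every generator and the permutation
  machinery are bit-reproducible given a seed.
- Probes with fewer than two present values in a group get NaN d and p
  and are excluded from the permutation pool.
- An all-zero standard-error panel yields s0 = 1e−6 with a warning;
  zero-variance paired differences report p at the machine floor with
  an infinite t.
- Floors: intensity ε = 1.0 before log2; π0 ≥ 1/m; |r| clipped to 1
  before the t transform with p reported at the machine floor for
  exact ±1.
- Problem sizes in the test suite were chosen so the full suite and
  the acceptance script each complete in minutes on a single CPU:
  20-seed benchmarks at full 962×64 design for the FDR and correlation
  checks, reduced designs (tens of probes, tens of samples) for unit
  tests, duplex oracle checks limited to ≤ 12 nt where exhaustive
  enumeration is exact and fast.

## Known limitations

- The screen models one loop-loop duplex per pair; coaxial stacking,
  dangling ends, AU-end penalties and partition-function ensembles are
  not modeled.
- The Nussinov baseline maximizes pair count, which over-pairs long
  sequences relative to thermodynamic folding; for realistic
  structures supply external predictions.
- Quantile normalization + log2 is a stand-in for RMA on the mRNA
  layer; no background deconvolution, loess or batch correction.
- Synthetic cohorts draw clinical covariates independently, so
  multi-contrast analyses on fixtures will not reproduce the
  confounding structure of real cohorts.
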