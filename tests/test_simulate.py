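import numpy as np
import pandas as pd
import pytest

from ucrna.containers import revcomp_dna, revcomp_rna
from ucrna.preprocess import preprocess_pipeline, summarize_replicates
from ucrna.simulate import (
    NoiseModel,
    dinucleotide_shuffle,
    gen_annotation,
    gen_correlated_layers,
    gen_expression,
    gen_gene_sets,
    gen_interacting_sequences,
    gen_ucr_catalog,
)
from conftest import make_matrix


class TestCatalog:
    def test_two_probes_per_ucr(self):
        loci, probes = gen_ucr_catalog(5, seed=0)
        assert len(loci) == 5 and len(probes) == 10

    def test_antisense_is_revcomp_of_sense(self):
        _, probes = gen_ucr_catalog(1, seed=3)
        sense, anti = probes
        assert anti.probe_sequence == revcomp_dna(sense.probe_sequence)
        assert sense.probe_id == "uc.1+" and anti.probe_id == "uc.1+A"

    def test_deterministic(self):
        a = gen_ucr_catalog(4, seed=9)
        b = gen_ucr_catalog(4, seed=9)
        assert [l.sequence for l in a[0]] == [l.sequence for l in b[0]]

    def test_minimum_length_rule(self):
        with pytest.raises(ValueError, match="200"):
            gen_ucr_catalog(1, length_range=(150, 300))


class TestAnnotation:
    def test_nontumor_clinical_fields_na(self):
        ann = gen_annotation(10, 3, seed=0)
        nt = ann[ann["tissue_class"] == "nontumor"]
        assert nt[["gleason_sum", "stage", "epe", "svi", "race"]].isna().all().all()
        assert len(nt) == 3

    def test_marginals_roughly_match_design(self):
        ann = gen_annotation(2000, 0, seed=1)
        assert (ann["gleason_sum"] >= 7).mean() == pytest.approx(0.77, abs=0.04)
        assert (ann["svi"] == "yes").mean() == pytest.approx(0.18, abs=0.04)


class TestExpression:
    def test_slide_layout(self):
        _, probes = gen_ucr_catalog(3, seed=0)
        spots, ann, _ = gen_expression(probes, cohort=(4, 2), n_blanks=10, seed=0)
        assert len(spots.slides) == 6
        one = spots.data[spots.data["slide_id"] == spots.slides[0]]
        assert len(one) == 4 * len(probes) + 10

    def test_zero_noise_replicates_identical(self):
        _, probes = gen_ucr_catalog(2, seed=0)
        noise = NoiseModel(sigma_sample=0.0, sigma_spot=0.0, background_mu=0.0,
                           background_sigma=0.0)
        spots, _, _ = gen_expression(probes, cohort=(3, 2), noise=noise, n_blanks=5, seed=0)
        per_probe = spots.probe_spots.groupby("probe_id")["raw_intensity"].nunique()
        assert (per_probe == 1).all()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(sigma_spot=-0.1)

    def test_unknown_effect_probe_rejected(self):
        _, probes = gen_ucr_catalog(1, seed=0)
        with pytest.raises(ValueError, match="unknown probe"):
            gen_expression(probes, effects=[("nope+", "tumor_vs_normal", 1.0)],
                           cohort=(3, 2), n_blanks=5)

    def test_planted_effect_recovered_in_summarized_means(self):
        """A planted 1.0 log2 effect appears as ~1.0 difference of group
        means after preprocessing (Monte Carlo over seeds)."""
        _, probes = gen_ucr_catalog(10, seed=0)
        target = probes[0].probe_id
        diffs = []
        for seed in range(12):
            spots, ann, _ = gen_expression(
                probes, cohort=(12, 6),
                effects=[(target, "tumor_vs_normal", 1.0)],
                n_blanks=30, seed=seed,
            )
            m, _ = preprocess_pipeline(spots)
            tum = ann.loc[ann["tissue_class"] == "tumor", "sample_id"]
            non = ann.loc[ann["tissue_class"] == "nontumor", "sample_id"]
            diffs.append(
                m.values.loc[target, tum].mean() - m.values.loc[target, non].mean()
            )
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - 1.0) < 3 * max(se, 0.02)


class TestCorrelatedLayers:
    def _source(self, n_samples=57, n_probes=4, seed=0):
        rng = np.random.default_rng(seed)
        return make_matrix(7 + rng.normal(size=(n_probes, n_samples)))

    def test_unplanted_rows_independent(self):
        src = self._source()
        mrna, _, _ = gen_correlated_layers(src, [], n_mrna=400, n_mir=5, seed=1)
        x = src.values.iloc[0].to_numpy()
        rs = [np.corrcoef(x, mrna.values.iloc[k])[0, 1] for k in range(400)]
        assert abs(np.mean(rs)) < 0.02

    def test_planted_r_realized(self):
        src = self._source()
        probe = src.probe_ids[0]
        mrna, _, truth = gen_correlated_layers(
            src, [(probe, "TGT", "mRNA", -0.8)], n_mrna=50, n_mir=5, seed=2
        )
        r = np.corrcoef(src.values.loc[probe], mrna.values.loc["TGT"])[0, 1]
        assert abs(r - (-0.8)) < 0.15
        assert truth.correlations.iloc[0]["true_r"] == -0.8

    def test_r_bounds_and_duplicates(self):
        src = self._source()
        probe = src.probe_ids[0]
        with pytest.raises(ValueError, match="< 1"):
            gen_correlated_layers(src, [(probe, "T", "mRNA", 1.0)], 10, 5)
        gen_correlated_layers(src, [(probe, "T", "mRNA", 0.99)], 10, 5)  # accepted
        with pytest.raises(ValueError, match="duplicate"):
            gen_correlated_layers(
                src, [(probe, "T", "mRNA", 0.5), (probe, "T", "miR", 0.5)], 10, 5
            )


class TestInteractingSequences:
    def test_loops_are_exact_revcomp(self):
        us, ms, truth = gen_interacting_sequences(1, loop_len=6, stem_len=4,
                                                  min_duplex_energy=-5.0, seed=0)
        from ucrna.structure import extract_loops

        [lu] = extract_loops(us[0], types={"hairpin"})
        [lm] = extract_loops(ms[0], types={"hairpin"})
        assert lm.subsequence == revcomp_rna(lu.subsequence)
        assert truth.interactions.iloc[0]["planted"]

    def test_deterministic_bytes(self, tmp_path):
        from ucrna import io

        for name in ("a", "b"):
            us, ms, _ = gen_interacting_sequences(3, n_decoys=2, seed=42)
            io.write_structures(
                tmp_path / f"{name}.txt",
                [(s.seq_id, s.sequence, s.dotbracket) for s in us + ms],
            )
        assert (tmp_path / "a.txt").read_bytes() == (tmp_path / "b.txt").read_bytes()

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="loop_len"):
            gen_interacting_sequences(1, loop_len=3)
        with pytest.raises(ValueError, match="stem_len"):
            gen_interacting_sequences(1, stem_len=2)
        with pytest.raises(ValueError, match="cannot reach"):
            gen_interacting_sequences(1, loop_len=4, min_duplex_energy=-10.0)

    def test_dinucleotide_shuffle_preserves_doublets(self, rng):
        seq = "GCAUGGCAUC"
        shuf = dinucleotide_shuffle(seq, rng)
        doublets = lambda s: sorted(s[i : i + 2] for i in range(len(s) - 1))
        assert doublets(shuf) == doublets(seq)
        assert shuf[0] == seq[0]


class TestGeneSets:
    def test_full_overlap(self):
        targets = {f"g{i}" for i in range(20)}
        universe = targets | {f"h{i}" for i in range(80)}
        gsc = gen_gene_sets(targets, universe, enriched_fraction=1.0, n_sets=3,
                            set_size=20, seed=0)
        enriched = dict((s, m) for s, _, m in gsc)["SET_ENRICHED"]
        assert len(enriched & targets) == 20

    def test_zero_sets(self):
        assert len(gen_gene_sets({"a"}, {"a", "b"}, n_sets=0)) == 0

    def test_fraction_validated(self):
        with pytest.raises(ValueError):
            gen_gene_sets({"a"}, {"a"}, enriched_fraction=1.5)
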