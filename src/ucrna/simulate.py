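"""Synthetic data generators with known ground truth.

Every generator is a pure, deterministic function of its arguments and
a seed.  The defaults emulate the study design this package targets: a
catalog of 481 ultraconserved regions (each with a sense and an
antisense 40-mer probe, 962 probesets), one-color arrays with
quadruplicate spots per probe plus 3484 blank spots, a cohort of 57
tumor and 7 non-tumor prostate samples with clinical covariates,
planted log2 differential effects, independent mRNA/miR layers with
planted correlations, and hairpin sequence pairs with complementary
loops for the interaction screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    BLANK,
    ExpressionMatrix,
    Probe,
    SpotTable,
    TruthTable,
    UcrLocus,
    dna_to_rna,
    revcomp_dna,
    revcomp_rna,
)
from .contrasts import STUDY_CONTRASTS, contrast_groups
from .duplex import full_complement_energy, load_params
from .io import GeneSetCollection
from .structure import RnaStructure

_BASES_DNA = np.array(list("ACGT"))
_BASES_RNA = "ACGU"

#: Table-1 marginal frequencies among the 57 tumors (drawn independently;
#: only the marginals are specified by the design being emulated).
CLINICAL_MARGINALS = {
    "gleason_ge7": 0.77,
    "stage_pt34": 0.51,
    "epe_yes": 0.42,
    "svi_yes": 0.18,
    "race_aa": 0.51,
}


# ---------------------------------------------------------------------------
# UCR catalog and probes


def gen_ucr_catalog(
    n_ucr: int = 481,
    length_range: tuple[int, int] = (200, 780),
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[UcrLocus], list[Probe]]:
    """Generate a UCR catalog and its sense/antisense 40-mer probes.

    Each UCR yields exactly two probes: the central genomic 40-mer
    (``uc.N+``) and its reverse complement (``uc.N+A``).
    """
    if n_ucr < 1:
        raise ValueError("n_ucr must be >= 1")
    lo, hi = length_range
    if lo < 200:
        raise ValueError("UCRs are defined as >200 bp; length_range.min must be >= 200")
    if class_mix is None:
        class_mix = {"nonexonic": 0.53, "exonic": 0.23, "possibly_exonic": 0.24}
    rng = np.random.default_rng(seed)
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    loci: list[UcrLocus] = []
    probes: list[Probe] = []
    for k in range(1, n_ucr + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES_DNA, size=length))
        ucr_class = classes[int(rng.choice(len(classes), p=probs))]
        host = f"GENE{k}" if ucr_class in ("exonic", "possibly_exonic") else None
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(0, 100_000_000))
        ucr_id = f"uc.{k}"
        loci.append(
            UcrLocus(
                ucr_id=ucr_id,
                chrom=chrom,
                start=start,
                end=start + length,
                ucr_class=ucr_class,
                host_gene=host,
                sequence=seq,
            )
        )
        off = (length - 40) // 2
        window = seq[off : off + 40]
        probes.append(Probe(f"{ucr_id}+", ucr_id, "sense", window))
        probes.append(Probe(f"{ucr_id}+A", ucr_id, "antisense", revcomp_dna(window)))
    return loci, probes


# ---------------------------------------------------------------------------
# Cohort annotation


def gen_annotation(
    n_tumor: int = 57, n_nontumor: int = 7, seed: int = 0
) -> pd.DataFrame:
    """Sample annotation with Table-1-style clinical marginals.

    Non-tumor samples carry NA in every clinical tumor field.
    Covariates are drawn independently at the stated marginal rates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    p = CLINICAL_MARGINALS
    for i in range(1, n_tumor + 1):
        gleason = int(rng.integers(7, 10)) if rng.random() < p["gleason_ge7"] else int(
            rng.integers(4, 7)
        )
        rows.append(
            {
                "sample_id": f"T{i:02d}",
                "tissue_class": "tumor",
                "gleason_sum": gleason,
                "stage": "pT3_4" if rng.random() < p["stage_pt34"] else "pT2",
                "epe": "yes" if rng.random() < p["epe_yes"] else "no",
                "svi": "yes" if rng.random() < p["svi_yes"] else "no",
                "race": "AA" if rng.random() < p["race_aa"] else "EA",
                "age_years": int(np.clip(round(rng.normal(61, 6)), 46, 73)),
            }
        )
    for i in range(1, n_nontumor + 1):
        rows.append(
            {
                "sample_id": f"N{i:02d}",
                "tissue_class": "nontumor",
                "gleason_sum": pd.NA,
                "stage": pd.NA,
                "epe": pd.NA,
                "svi": pd.NA,
                "race": pd.NA,
                "age_years": int(np.clip(round(rng.normal(61, 6)), 46, 73)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spot-level expression


@dataclass(frozen=True)
class NoiseModel:
    """Log-normal signal noise plus additive scanner background.

    sigma_sample: per-sample log2 shift (array/biology effect).
    sigma_spot:   per-spot log2 replicate noise.
    background:   Normal(mu, sigma) truncated at 0, added to every spot
                  and the sole source of blank-spot intensity.
    """

    sigma_sample: float = 0.3
    sigma_spot: float = 0.25
    background_mu: float = 50.0
    background_sigma: float = 10.0

    def __post_init__(self) -> None:
        for name in ("sigma_sample", "sigma_spot", "background_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def gen_expression(
    probes: list[Probe],
    cohort: tuple[int, int] = (57, 7),
    effects: list[tuple[str, str, float]] | None = None,
    noise: NoiseModel | None = None,
    n_blanks: int = 3484,
    n_replicates: int = 4,
    seed: int = 0,
    baseline_log2_range: tuple[float, float] = (6.0, 12.0),
) -> tuple[SpotTable, pd.DataFrame, TruthTable]:
    """Simulate one slide per sample at the spot level.

    Per spot: ``raw = 2**(b_i + sum(effect * indicator) + u_s + eps) + bg``
    with ``eps ~ N(0, sigma_spot)``, ``u_s ~ N(0, sigma_sample)`` and
    ``bg`` a truncated-normal background draw; blank spots are drawn
    from the background distribution only.  ``effects`` are
    ``(probe_id, contrast_name, log2_effect)`` applied to the contrast's
    case group.
    """
    if noise is None:
        noise = NoiseModel()
    effects = effects or []
    probe_ids = [p.probe_id for p in probes]
    probe_index = {pid: k for k, pid in enumerate(probe_ids)}
    for pid, _, _ in effects:
        if pid not in probe_index:
            raise ValueError(f"effect refers to unknown probe {pid!r}")

    n_tumor, n_nontumor = cohort
    rng = np.random.default_rng(seed)
    ann = gen_annotation(n_tumor, n_nontumor, seed=int(rng.integers(2**31)))
    sample_ids = ann["sample_id"].tolist()
    P, S, R = len(probes), len(sample_ids), n_replicates

    effect_mat = np.zeros((P, S))
    for pid, contrast_name, log2_effect in effects:
        contrast = STUDY_CONTRASTS[contrast_name]
        _, case = contrast_groups(ann, contrast)
        cols = [sample_ids.index(s) for s in case]
        effect_mat[probe_index[pid], cols] += log2_effect

    b = rng.uniform(*baseline_log2_range, size=P)
    u = rng.normal(0.0, noise.sigma_sample, size=S) if noise.sigma_sample else np.zeros(S)
    eps = (
        rng.normal(0.0, noise.sigma_spot, size=(P, S, R))
        if noise.sigma_spot
        else np.zeros((P, S, R))
    )
    log2_signal = b[:, None, None] + effect_mat[:, :, None] + u[None, :, None] + eps
    bg = np.clip(
        rng.normal(noise.background_mu, noise.background_sigma, size=(P, S, R)), 0, None
    )
    raw = np.exp2(log2_signal) + bg
    bg_blank = np.clip(
        rng.normal(noise.background_mu, noise.background_sigma, size=(n_blanks, S)),
        0,
        None,
    )

    # assemble sample-major: per slide, all probe spots then all blanks
    probe_arr = np.asarray(probe_ids)
    frames = []
    for s_idx, sid in enumerate(sample_ids):
        n_probe_rows = P * R
        reps = np.tile(np.arange(1, R + 1), P)
        pid_col = np.repeat(probe_arr, R)
        spot_ids = np.char.add(
            np.char.add(f"{sid}:", pid_col.astype(str)),
            np.char.add(":", reps.astype(str)),
        )
        frames.append(
            pd.DataFrame(
                {
                    "slide_id": sid,
                    "spot_id": spot_ids,
                    "probe_id": pid_col,
                    "replicate_index": reps,
                    "raw_intensity": raw[:, s_idx, :].reshape(n_probe_rows),
                    "flag": "ok",
                }
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "slide_id": sid,
                    "spot_id": [f"{sid}:BLANK:{k}" for k in range(1, n_blanks + 1)],
                    "probe_id": BLANK,
                    "replicate_index": 1,
                    "raw_intensity": bg_blank[:, s_idx],
                    "flag": "ok",
                }
            )
        )
    spots = SpotTable(pd.concat(frames, ignore_index=True))
    truth = TruthTable(
        effects=pd.DataFrame(
            effects, columns=["probe_id", "contrast", "true_log2_effect"]
        )
    )
    return spots, ann, truth


# ---------------------------------------------------------------------------
# Correlated mRNA / miR layers


def gen_correlated_layers(
    ucrna_matrix: ExpressionMatrix,
    spec: list[tuple[str, str, str, float]] | None = None,
    n_mrna: int = 1000,
    n_mir: int = 238,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TruthTable]:
    """Generate mRNA and miR layers over the same samples.

    ``spec`` rows are ``(ucrna_probe, target_id, layer, r)``.  A planted
    target equals ``r * standardized(source) + sqrt(1-r^2) * noise``
    (plus a baseline), so its population correlation with the source is
    exactly ``r``; all unplanted rows are independent of the ucRNA layer.
    """
    spec = spec or []
    rng = np.random.default_rng(seed)
    samples = ucrna_matrix.sample_ids
    S = len(samples)
    seen = set()
    for source, target, layer, r in spec:
        if abs(r) >= 1:
            raise ValueError(f"planted |r| must be < 1, got {r} for {target!r}")
        if layer not in ("mRNA", "miR"):
            raise ValueError(f"unknown layer {layer!r}")
        if (source, target) in seen:
            raise ValueError(f"duplicate planted pair ({source!r}, {target!r})")
        if source not in ucrna_matrix.values.index:
            raise ValueError(f"unknown source probe {source!r}")
        seen.add((source, target))

    def build(layer_name: str, n_rows: int, prefix: str) -> pd.DataFrame:
        planted = [(s, t, r) for s, t, l, r in spec if l == layer_name]
        planted_ids = [t for _, t, _ in planted]
        if len(planted_ids) != len(set(planted_ids)):
            raise ValueError("planted targets must be distinct within a layer")
        n_free = n_rows - len(planted_ids)
        if n_free < 0:
            raise ValueError(f"{layer_name}: more planted targets than rows")
        ids = planted_ids + [f"{prefix}{k:05d}" for k in range(1, n_free + 1)]
        vals = 7.0 + rng.normal(0.0, 1.0, size=(n_rows, S))
        for row, (source, _, r) in enumerate(planted):
            x = ucrna_matrix.values.loc[source].to_numpy(dtype=float)
            z = (x - np.nanmean(x)) / np.nanstd(x)
            vals[row] = 7.0 + r * z + np.sqrt(1 - r * r) * rng.normal(0.0, 1.0, size=S)
        return pd.DataFrame(vals, index=ids, columns=samples)

    mrna = ExpressionMatrix.from_values(build("mRNA", n_mrna, "MRNA"))
    mir = ExpressionMatrix.from_values(build("miR", n_mir, "MIR"))
    truth = TruthTable(
        correlations=pd.DataFrame(
            [(s, t, l, r) for s, t, l, r in spec],
            columns=["source_id", "target_id", "layer", "true_r"],
        )
    )
    return mrna, mir, truth


# ---------------------------------------------------------------------------
# Interacting hairpin fixtures


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Shuffle ``seq`` preserving dinucleotide composition (random
    Eulerian walk over the doublet graph)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for x, y in zip(seq, seq[1:]):
        edges.setdefault(x, []).append(y)
    n_edges = len(seq) - 1
    for _ in range(max_tries):
        remaining = {k: list(v) for k, v in edges.items()}
        out = [seq[0]]
        cur = seq[0]
        ok = True
        for _ in range(n_edges):
            choices = remaining.get(cur, [])
            if not choices:
                ok = False
                break
            nxt = choices.pop(int(rng.integers(len(choices))))
            out.append(nxt)
            cur = nxt
        if ok:
            return "".join(out)
    return seq  # degenerate sequences may admit no other walk


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES_RNA[i] for i in rng.integers(0, 4, size=length))


def _hairpin(seq_id: str, rng, loop: str, stem_len: int, flank_len: int) -> RnaStructure:
    # stems pair by construction (Watson-Crick), flanks are left unpaired
    stem = _random_rna(rng, stem_len)
    f5 = _random_rna(rng, flank_len)
    f3 = _random_rna(rng, flank_len)
    seq = f5 + stem + loop + revcomp_rna(stem) + f3
    db = (
        "." * flank_len
        + "(" * stem_len
        + "." * len(loop)
        + ")" * stem_len
        + "." * flank_len
    )
    return RnaStructure(seq_id, seq, db)


def gen_interacting_sequences(
    n_pairs: int,
    loop_len: int = 10,
    stem_len: int = 6,
    n_decoys: int = 0,
    seed: int = 0,
    flank_len: int = 20,
    min_duplex_energy: float = -10.0,
) -> tuple[list[RnaStructure], list[RnaStructure], TruthTable]:
    """Hairpin pairs with exactly complementary loops, plus shuffled decoys.

    Each planted pair is a ucRNA hairpin and an mRNA hairpin whose loop
    is the exact RNA reverse complement of the ucRNA loop.  Planted
    loops are drawn until their full-complement duplex energy under the
    bundled nearest-neighbor table is at most ``min_duplex_energy``, so
    a planted interaction is by construction a stable one.  Decoys are
    extra mRNA hairpins whose loops are dinucleotide shuffles of
    planted loops.  Dot-bracket structures are emitted alongside.
    """
    if loop_len < 4:
        raise ValueError("loop_len must be >= 4")
    if stem_len < 3:
        raise ValueError("stem_len must be >= 3 (unstable hairpin fixture)")
    params = load_params()
    best_possible = params.init + (loop_len - 1) * min(params.stacks.values())
    if best_possible > min_duplex_energy:
        raise ValueError(
            f"loop_len={loop_len} cannot reach duplex energy {min_duplex_energy} "
            f"kcal/mol (best possible {best_possible:.2f}); increase loop_len"
        )
    rng = np.random.default_rng(seed)
    ucrnas: list[RnaStructure] = []
    mrnas: list[RnaStructure] = []
    truth_rows = []
    planted_loops: list[str] = []
    for k in range(1, n_pairs + 1):
        for _ in range(1000):
            loop_u = _random_rna(rng, loop_len)
            if full_complement_energy(loop_u, params) <= min_duplex_energy:
                break
        else:  # pragma: no cover - essentially unreachable at sane settings
            raise RuntimeError("failed to draw a stable planted loop")
        uid, mid = f"uc.{k}+", f"MRNA{k:04d}"
        ucrnas.append(_hairpin(uid, rng, loop_u, stem_len, flank_len))
        loop_m = revcomp_rna(loop_u)
        mrnas.append(_hairpin(mid, rng, loop_m, stem_len, flank_len))
        planted_loops.append(loop_m)
        truth_rows.append((uid, mid, True))
    for d in range(1, n_decoys + 1):
        template = planted_loops[(d - 1) % len(planted_loops)]
        decoy_loop = template
        for _ in range(50):
            decoy_loop = dinucleotide_shuffle(template, rng)
            if decoy_loop != template:
                break
        else:
            decoy_loop = _random_rna(rng, loop_len)
        mrnas.append(_hairpin(f"DECOY{d:04d}", rng, decoy_loop, stem_len, flank_len))
    truth = TruthTable(
        interactions=pd.DataFrame(truth_rows, columns=["ucrna_id", "mrna_id", "planted"])
    )
    return ucrnas, mrnas, truth


# ---------------------------------------------------------------------------
# Gene sets


def gen_gene_sets(
    targets: set[str],
    universe: set[str],
    enriched_fraction: float = 0.8,
    n_sets: int = 20,
    set_size: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets plus one designated set overlapping ``targets``
    at ``enriched_fraction`` of its size."""
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must lie in [0,1]")
    if not set(targets) <= set(universe):
        raise ValueError("targets must be a subset of the universe")
    rng = np.random.default_rng(seed)
    universe_list = sorted(universe)
    targets_list = sorted(targets)
    non_targets = sorted(set(universe) - set(targets))
    sets = []
    if n_sets >= 1:
        k = round(enriched_fraction * set_size)
        k = min(k, len(targets_list))
        fill = set_size - k
        members = list(rng.choice(targets_list, size=k, replace=False)) + list(
            rng.choice(non_targets, size=min(fill, len(non_targets)), replace=False)
        )
        sets.append(("SET_ENRICHED", "designated enriched set", frozenset(members)))
    for i in range(2, n_sets + 1):
        members = rng.choice(universe_list, size=min(set_size, len(universe_list)), replace=False)
        sets.append((f"SET{i:03d}", "random set", frozenset(members)))
    return GeneSetCollection(sets)


def sequences_from_catalog(loci: list[UcrLocus]) -> list[tuple[str, str]]:
    """FASTA-ready (id, sequence) records for a catalog's transcripts
    (sense only; the genomic sequence, RNA alphabet)."""
    return [(loc.ucr_id, dna_to_rna(loc.sequence)) for loc in loci]
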