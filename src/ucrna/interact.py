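"""The loop-loop (kissing) interaction screen and target enrichment.

Candidate ucRNA:mRNA interactions are modeled as a single
intermolecular duplex between the unpaired loop bases of the two
folded RNAs.  For each sequence pair, loops are extracted from both
structures, every loop x loop combination is scored with the
nearest-neighbor duplex model, and the best duplex is kept.  A pair
passes the screen when the duplex is stable (``delta_g <=
energy_cutoff``, default -10 kcal/mol) and dense (``bond_fraction``
strictly greater than the cutoff, default 0.75 of the shorter loop) --
the strict ">75% of bonds" reading.  Predicted target sets are tested
for gene-set enrichment with upper-tail hypergeometric p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .duplex import DuplexPrediction, NnParams, duplex_energy, load_params
from .io import GeneSetCollection
from .structure import RnaStructure, extract_loops


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and loop-extraction settings for the screen."""

    energy_cutoff: float = -10.0  # kcal/mol; pass requires delta_g <= cutoff
    bond_fraction_cutoff: float = 0.75  # strict: pass requires bf > cutoff
    min_loop_len: int = 4
    loop_types: frozenset = frozenset({"hairpin"})
    denominator: str = "shorter"  # bond-fraction reference

    def __post_init__(self) -> None:
        if not (0.0 < self.bond_fraction_cutoff < 1.0):
            raise ValueError("bond_fraction_cutoff must lie in (0,1)")


@dataclass
class InteractionPair:
    ucrna_id: str
    mrna_id: str
    best_duplex: DuplexPrediction | None  # None: no pairable loops at all
    passes: bool


def evaluate_pair(
    u: RnaStructure,
    m: RnaStructure,
    cfg: ScreenConfig | None = None,
    params: NnParams | None = None,
) -> InteractionPair:
    """Best loop-loop duplex between two structures and the pass flag.

    All loop x loop combinations are scored; the best duplex has the
    lowest delta_g, with ties broken by larger bond fraction and then
    by loop order (first loop of u, then of m).
    """
    if cfg is None:
        cfg = ScreenConfig()
    if params is None:
        params = load_params()
    loops_u = extract_loops(u, cfg.min_loop_len, set(cfg.loop_types))
    loops_m = extract_loops(m, cfg.min_loop_len, set(cfg.loop_types))
    best = None
    for lu in loops_u:
        for lm in loops_m:
            dp = duplex_energy(
                lu.subsequence, lm.subsequence, params, cfg.denominator
            )
            if dp is None:
                continue
            dp.loop_a, dp.loop_b = lu, lm
            if best is None or (
                (dp.delta_g, -dp.bond_fraction) < (best.delta_g, -best.bond_fraction)
            ):
                best = dp
    if best is None:
        return InteractionPair(u.seq_id, m.seq_id, None, False)
    passes = best.delta_g <= cfg.energy_cutoff and (
        best.bond_fraction > cfg.bond_fraction_cutoff
    )
    return InteractionPair(u.seq_id, m.seq_id, best, passes)


@dataclass
class ScreenSummary:
    n_pairs: int
    n_distinct_ucrnas: int
    n_distinct_mrnas: int
    n_evaluated: int = 0


def screen_interactions(
    ucrnas: list[RnaStructure],
    mrnas: list[RnaStructure],
    cfg: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, ScreenSummary]:
    """All-vs-all loop-loop screen.

    Returns the passing pairs as a table sorted by (ucrna_id, mrna_id)
    -- output is therefore invariant to input file ordering -- and a
    summary with distinct-entity counts.
    """
    if not ucrnas or not mrnas:
        raise ValueError("both structure collections must be non-empty")
    if cfg is None:
        cfg = ScreenConfig()
    params = load_params()
    rows = []
    for u in ucrnas:
        for m in mrnas:
            pair = evaluate_pair(u, m, cfg, params)
            if pair.passes:
                d = pair.best_duplex
                rows.append(
                    {
                        "ucrna_id": pair.ucrna_id,
                        "mrna_id": pair.mrna_id,
                        "delta_g": d.delta_g,
                        "bond_fraction": d.bond_fraction,
                        "n_pairs": len(d.paired_positions),
                    }
                )
    table = pd.DataFrame(
        rows, columns=["ucrna_id", "mrna_id", "delta_g", "bond_fraction", "n_pairs"]
    ).sort_values(["ucrna_id", "mrna_id"], kind="mergesort").reset_index(drop=True)
    summary = ScreenSummary(
        n_pairs=len(table),
        n_distinct_ucrnas=table["ucrna_id"].nunique(),
        n_distinct_mrnas=table["mrna_id"].nunique(),
        n_evaluated=len(ucrnas) * len(mrnas),
    )
    return table, summary


def enrich_targets(
    targets: set[str],
    universe: set[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``targets`` in each gene set.

    Sets are intersected with the universe; p = P[X >= overlap] with
    population ``|universe|``, successes ``|set|`` and draws
    ``|targets|``; Benjamini-Hochberg adjusted p across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(targets) <= set(universe):
        raise ValueError("targets must be a subset of the universe")
    M = len(universe)
    N = len(targets)
    rows = []
    for set_id, _desc, members in sets:
        inter = set(members) & set(universe)
        if not inter:
            continue
        K = len(inter)
        k = len(inter & set(targets))
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {
                "set_id": set_id,
                "overlap": k,
                "set_size": K,
                "n_targets": N,
                "universe_size": M,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set_id", "overlap", "set_size", "n_targets", "universe_size", "p_value"],
    )
    if len(df):
        df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["adjusted_p"] = []
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
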