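"""Pearson correlation analyses across expression layers.

Three views: host-gene pair correlations with a distribution summary
(the null-shaped cloud of ucRNA vs UCR-encoded mRNA pairs), per-ucRNA
genome-wide scans against an mRNA or miR layer, and sense/antisense
probe concordance per UCR.  Significance uses the exact t transform
``t = r sqrt((n-2)/(1-r^2))`` with two-sided p; missing cells are
handled pairwise-complete with the used sample count recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with two-sided p via the t transform."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, np.finfo(float).tiny, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


@dataclass
class PairDistributionSummary:
    """Distribution of pairwise correlations (Fig-3-style summary)."""

    n_pairs: int
    mean_r: float
    sd_r: float
    fraction_within: float  # fraction with -0.2 < r < 0.2
    skipped_pairs: list = field(default_factory=list)


def pair_correlations(
    ucrna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    band: tuple[float, float] = (-0.2, 0.2),
) -> tuple[pd.DataFrame, PairDistributionSummary]:
    """Pearson r for each (ucrna_probe, mrna_id) pair over shared samples.

    Pairs with fewer than 3 shared complete samples are skipped and
    reported in the summary.
    """
    shared = [s for s in ucrna.sample_ids if s in set(mrna.sample_ids)]
    if len(shared) < 3:
        raise ValueError("layers share fewer than 3 samples")
    records = []
    skipped = []
    for src, tgt in pairs:
        if src not in ucrna.values.index:
            raise ValueError(f"unknown ucRNA probe {src!r}")
        if tgt not in mrna.values.index:
            raise ValueError(f"unknown mRNA id {tgt!r}")
        x = ucrna.values.loc[src, shared].to_numpy(dtype=float)
        y = mrna.values.loc[tgt, shared].to_numpy(dtype=float)
        r, p, n = _pearson_with_p(x, y)
        if np.isnan(r):
            skipped.append((src, tgt, n))
            continue
        records.append(
            {"source_id": src, "target_id": tgt, "layer": "mRNA", "r": r,
             "p_value": p, "n_used": n}
        )
    rec = pd.DataFrame(records, columns=["source_id", "target_id", "layer", "r",
                                         "p_value", "n_used"])
    rs = rec["r"].to_numpy(dtype=float)
    lo, hi = band
    summary = PairDistributionSummary(
        n_pairs=len(rec),
        mean_r=float(np.mean(rs)) if len(rs) else np.nan,
        sd_r=float(np.std(rs, ddof=1)) if len(rs) > 1 else np.nan,
        fraction_within=float(np.mean((rs > lo) & (rs < hi))) if len(rs) else np.nan,
        skipped_pairs=skipped,
    )
    return rec, summary


def global_scan(
    source: pd.Series,
    layer: ExpressionMatrix,
    layer_name: str = "mRNA",
    adjust: str = "none",
) -> pd.DataFrame:
    """Correlate one probe's values against every row of a layer.

    Returns records sorted by |r| descending; raw p is always reported
    and a Benjamini-Hochberg step-up adjusted column is appended when
    ``adjust="step-up"``.
    """
    shared = [s for s in source.index if s in set(layer.sample_ids)]
    if len(shared) < 3:
        raise ValueError("layer shares fewer than 3 samples with the source")
    x = source[shared].to_numpy(dtype=float)
    if np.nanstd(x) == 0:
        raise ValueError("zero-variance source probe")
    L = layer.values[shared].to_numpy(dtype=float)
    okx = ~np.isnan(x)
    oky = ~np.isnan(L)
    ok = oky & okx[None, :]
    n_used = ok.sum(axis=1)
    xz = np.where(okx, x, 0.0)
    Lz = np.where(oky, L, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_x = (ok * xz[None, :]).sum(axis=1)
        sum_y = (Lz * ok).sum(axis=1)
        sum_xx = (ok * xz[None, :] ** 2).sum(axis=1)
        sum_yy = (Lz**2 * ok).sum(axis=1)
        sum_xy = (Lz * xz[None, :] * ok).sum(axis=1)
        n = n_used.astype(float)
        cov = sum_xy - sum_x * sum_y / n
        varx = sum_xx - sum_x**2 / n
        vary = sum_yy - sum_y**2 / n
        r = cov / np.sqrt(varx * vary)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p = np.where(np.abs(r) == 1.0, np.finfo(float).tiny, p)
    bad = (n_used < 3) | np.isnan(r)
    rec = pd.DataFrame(
        {
            "source_id": source.name,
            "target_id": layer.values.index,
            "layer": layer_name,
            "r": np.where(bad, np.nan, r),
            "p_value": np.where(bad, np.nan, p),
            "n_used": n_used,
        }
    )
    rec = rec.dropna(subset=["r"])
    if adjust == "step-up":
        rec["p_adjusted"] = multipletests(rec["p_value"], method="fdr_bh")[1]
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return rec.reindex(rec["r"].abs().sort_values(ascending=False, kind="mergesort").index).reset_index(
        drop=True
    )


def sense_antisense_concordance(ucrna: ExpressionMatrix) -> pd.DataFrame:
    """Pearson r between the "+" and "+A" probes of each UCR.

    UCRs missing either strand probe are skipped (reported with NaN r).
    """
    rows = []
    index = set(ucrna.values.index)
    ucr_ids = sorted(
        {pid[:-1] for pid in index if pid.endswith("+")},
        key=lambda u: (len(u), u),
    )
    for ucr in ucr_ids:
        sense, anti = f"{ucr}+", f"{ucr}+A"
        if anti not in index:
            rows.append({"ucr_id": ucr, "r": np.nan, "p_value": np.nan, "n_used": 0})
            continue
        x = ucrna.values.loc[sense].to_numpy(dtype=float)
        y = ucrna.values.loc[anti].to_numpy(dtype=float)
        r, p, n = _pearson_with_p(x, y)
        rows.append({"ucr_id": ucr, "r": r, "p_value": p, "n_used": n})
    return pd.DataFrame(rows)
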