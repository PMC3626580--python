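"""Spot-level preprocessing: background subtraction against blank spots,
replicate summarization, median-centric normalization, probe filtering;
plus quantile normalization for the mRNA layer and reference-gene
scaling for count-based validation data.

The pipeline order is fixed: subtract -> summarize -> median-center ->
filter.  Each stage is idempotent where that is meaningful and filtering
never alters surviving values, only membership and masks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BLANK, ExpressionMatrix, SpotTable

LOG_FLOOR = 1.0  # intensity floor applied after background subtraction


def subtract_background(spots: SpotTable, floor: float = LOG_FLOOR) -> SpotTable:
    """Subtract each slide's median blank intensity from its probe spots.

    Results are floored at a small positive ``floor`` (default 1.0) so
    the subsequent log2 transform is defined.  A slide without blanks
    is an error naming the slide.
    """
    df = spots.data.copy()
    blanks = df[df["probe_id"] == BLANK]
    medians = blanks.groupby("slide_id")["raw_intensity"].median()
    for slide in spots.slides:
        if slide not in medians.index:
            raise ValueError(f"slide {slide!r} has no blank spots")
    is_probe = df["probe_id"] != BLANK
    adj = df.loc[is_probe, "raw_intensity"] - df.loc[is_probe, "slide_id"].map(medians)
    df.loc[is_probe, "raw_intensity"] = np.maximum(adj, floor)
    return SpotTable(df, list(spots.warnings))


def summarize_replicates(spots: SpotTable) -> ExpressionMatrix:
    """log2 of the median across a probe's non-flagged replicate spots.

    One column per slide (slide == sample).  Probes whose replicates
    are all flagged get a "filtered" cell; probes absent from a slide
    get "missing".
    """
    probes = spots.probe_spots
    ok = probes[probes["flag"] == "ok"]
    med = ok.groupby(["probe_id", "slide_id"])["raw_intensity"].median()
    values = np.log2(med).unstack("slide_id")
    all_probes = pd.Index(pd.unique(probes["probe_id"]), name="probe_id")
    all_slides = pd.Index(spots.slides, name="slide_id")
    values = values.reindex(index=all_probes, columns=all_slides)
    # distinguish "had spots but all flagged" from "never printed"
    printed = probes.groupby(["probe_id", "slide_id"]).size().unstack("slide_id")
    printed = printed.reindex(index=all_probes, columns=all_slides).fillna(0) > 0
    mask = np.where(
        ~np.isnan(values.to_numpy()),
        "present",
        np.where(printed.to_numpy(), "filtered", "missing"),
    )
    values.columns.name = None
    values.index.name = None
    return ExpressionMatrix(
        values, pd.DataFrame(mask, index=values.index, columns=values.columns)
    )


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Shift each sample so its median (over present cells) equals the
    global median of per-sample medians.  Idempotent."""
    vals = m.values.to_numpy(dtype=float).copy()
    present = m.present.to_numpy()
    if (~present).all(axis=0).any():
        bad = m.sample_ids[int(np.argmax((~present).all(axis=0)))]
        raise ValueError(f"sample {bad!r} has no present values")
    work = np.where(present, vals, np.nan)
    sample_medians = np.nanmedian(work, axis=0)
    target = np.median(sample_medians)
    vals = vals + (target - sample_medians)[None, :]
    vals[~present] = np.nan
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.values.index, columns=m.values.columns), m.mask.copy()
    )


def filter_probes(
    m: ExpressionMatrix,
    intensity_floor: float = 1.0,
    min_fold_change: float = 1.2,
    max_missing_fraction: float = 0.5,
) -> tuple[ExpressionMatrix, list[str]]:
    """Apply the low-intensity and minimum-fold-change filters, then drop
    probes with at least ``max_missing_fraction`` missing-or-filtered
    cells.  Returns the filtered matrix and the dropped probe ids.

    ``intensity_floor`` is on the log2 scale; the fold-change rule
    filters a whole probe row when max/min over present cells (linear
    ratio) is below ``min_fold_change``.  Surviving values are never
    altered.
    """
    vals = m.values.to_numpy(dtype=float).copy()
    mask = m.mask.to_numpy().copy()
    low = (mask == "present") & (vals < intensity_floor)
    mask[low] = "filtered"
    vals[low] = np.nan
    work = np.where(mask == "present", vals, np.nan)
    with np.errstate(all="ignore"):
        span = np.nanmax(work, axis=1) - np.nanmin(work, axis=1)
    flat = span < np.log2(min_fold_change)
    flat &= ~np.isnan(span)
    mask[flat, :] = np.where(mask[flat, :] == "present", "filtered", mask[flat, :])
    vals[flat, :] = np.nan
    bad_frac = (mask != "present").mean(axis=1)
    keep = bad_frac < max_missing_fraction
    dropped = [pid for pid, k in zip(m.probe_ids, keep) if not k]
    out = ExpressionMatrix(
        pd.DataFrame(vals[keep], index=m.values.index[keep], columns=m.values.columns),
        pd.DataFrame(mask[keep], index=m.values.index[keep], columns=m.values.columns),
    )
    return out, dropped


def preprocess_pipeline(
    spots: SpotTable,
    intensity_floor: float = 1.0,
    min_fold_change: float = 1.2,
) -> tuple[ExpressionMatrix, list[str]]:
    """subtract_background -> summarize_replicates -> median_center ->
    filter_probes, returning the final matrix and dropped probe ids."""
    m = summarize_replicates(subtract_background(spots))
    m = median_center(m)
    return filter_probes(m, intensity_floor, min_fold_change)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution given by the
    row-wise mean of sorted columns; ties receive the average value.

    Requires a complete matrix (mask all "present"); callers with
    masked cells must impute or drop first.
    """
    if (m.mask.to_numpy() != "present").any():
        raise ValueError(
            "quantile_normalize requires a complete matrix; impute or drop "
            "masked cells first"
        )
    vals = m.values.to_numpy(dtype=float)
    order = np.sort(vals, axis=0)
    mean_sorted = order.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = pd.Series(vals[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (mean_sorted[lo] + mean_sorted[hi])
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), m.mask.copy()
    )


def normalize_reference_counts(
    counts: pd.DataFrame, reference_id: str
) -> pd.DataFrame:
    """Scale each sample so its reference-gene count equals the
    across-sample geometric mean of reference counts (the GUSB-style
    normalization used for count-based validation assays)."""
    if reference_id not in counts.index:
        raise ValueError(f"reference {reference_id!r} not in count table")
    ref = counts.loc[reference_id].astype(float)
    if (ref <= 0).any():
        bad = ref.index[ref <= 0][0]
        raise ValueError(f"reference count is zero in sample {bad!r}")
    geo = float(np.exp(np.log(ref).mean()))
    return counts.astype(float) * (geo / ref)
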