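"""SAM-style class comparison with permutation p-values and Storey
q-values, plus the randomized-block t-test and the comparative-CT
qPCR fold change.

The moderated statistic is ``d_i = (mean_B - mean_A) / (s_i + s0)``
where ``s_i`` is the pooled two-sample standard error and ``s0`` a
fudge factor that stabilizes the variance of ``d`` across expression
levels.  Significance comes from a pooled permutation null: class
labels are permuted B times and the permuted ``|d|`` of *all* probes
form one null pool, which gives usable resolution at small B.  False
discovery rates follow the Storey-Tibshirani q-value estimator with
pi0 estimated at a fixed lambda by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .contrasts import STUDY_CONTRASTS, Contrast, contrast_groups


@dataclass(frozen=True)
class SamConfig:
    """Settings for the permutation class comparison."""

    s0: float | None = None  # None -> median of s_i
    permutations: int = 200
    two_sided: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValueError("permutation count must be >= 1")
        if self.s0 is not None and self.s0 < 0:
            raise ValueError("s0 must be non-negative")


def _group_stats(vals: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, ...]:
    """NaN-aware per-probe (mean, sum-of-squares, count) for one group."""
    sub = vals[:, cols]
    n = np.sum(~np.isnan(sub), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(sub, axis=1)
        ss = np.nansum((sub - mean[:, None]) ** 2, axis=1)
    return mean, ss, n


def fold_change(
    m: ExpressionMatrix, group_a: list[str], group_b: list[str]
) -> pd.Series:
    """Linear fold change 2^(mean_B - mean_A) per probe over present
    cells; NaN where a group has no present cell."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    vals = m.values.to_numpy(dtype=float)
    cols = {s: k for k, s in enumerate(m.sample_ids)}
    ia = np.array([cols[s] for s in group_a])
    ib = np.array([cols[s] for s in group_b])
    mean_a, _, na = _group_stats(vals, ia)
    mean_b, _, nb = _group_stats(vals, ib)
    fc = np.exp2(mean_b - mean_a)
    fc[(na == 0) | (nb == 0)] = np.nan
    return pd.Series(fc, index=m.values.index, name="fold_change")


def sam_d_statistic(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    s0: float,
) -> tuple[pd.Series, pd.Series]:
    """Per-probe (d_i, s_i) with
    ``s_i = sqrt((1/n_A + 1/n_B) (SS_A + SS_B) / (n_A + n_B - 2))``.

    Requires at least two usable samples per group overall; probes with
    fewer than two present values in a group get NaN.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            "each group needs >= 2 samples; for single-replicate designs use "
            "block_t_test"
        )
    vals = m.values.to_numpy(dtype=float)
    cols = {s: k for k, s in enumerate(m.sample_ids)}
    ia = np.array([cols[s] for s in group_a])
    ib = np.array([cols[s] for s in group_b])
    d, s = _d_and_s(vals, ia, ib, s0)
    return (
        pd.Series(d, index=m.values.index, name="d"),
        pd.Series(s, index=m.values.index, name="s"),
    )


def _d_and_s(vals, ia, ib, s0):
    mean_a, ss_a, na = _group_stats(vals, ia)
    mean_b, ss_b, nb = _group_stats(vals, ib)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (1.0 / na + 1.0 / nb) * (ss_a + ss_b) / (na + nb - 2.0)
        s = np.sqrt(pooled)
        d = (mean_b - mean_a) / (s + s0)
    bad = (na < 2) | (nb < 2)
    d[bad] = np.nan
    s[bad] = np.nan
    return d, s


def choose_s0(s_values: np.ndarray, policy: str = "median") -> float:
    """Fudge factor from the distribution of per-probe standard errors.

    Default is the median of ``s_i``; if every ``s_i`` is zero a small
    positive constant is returned with a warning.  (A full percentile
    search in the style of the original SAM procedure is possible but
    the median is stable on probe lists of this size and keeps the
    statistic's ranking monotone for constant-variance data.)
    """
    s = np.asarray(s_values, dtype=float)
    s = s[~np.isnan(s)]
    if len(s) < 10:
        raise ValueError("need >= 10 probes to choose s0")
    if policy != "median":
        raise ValueError(f"unknown s0 policy {policy!r}")
    s0 = float(np.median(s))
    if s0 == 0.0:
        warnings.warn("all standard errors zero; using s0 = 1e-6")
        return 1e-6
    return s0


def _distinct_label_permutations(n: int, k: int) -> int:
    return math.comb(n, k)


def permutation_pvalues(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    cfg: SamConfig,
    s0: float,
    d_obs: np.ndarray | None = None,
) -> pd.Series:
    """Pooled-null permutation p-values for the SAM statistic.

    Class labels are permuted ``cfg.permutations`` times (seeded; B is
    truncated with a warning if it exceeds the number of distinct
    permutations, in which case the distinct assignments are
    enumerated).  The permuted d of all probes form one null pool and
    ``p_i = (1 + #{null |d| >= |d_i|}) / (1 + B * n_probes)``.
    """
    vals = m.values.to_numpy(dtype=float)
    cols = {s: k for k, s in enumerate(m.sample_ids)}
    ia = np.array([cols[s] for s in group_a])
    ib = np.array([cols[s] for s in group_b])
    if d_obs is None:
        d_obs, _ = _d_and_s(vals, ia, ib, s0)
    all_cols = np.concatenate([ia, ib])
    n_tot, n_a = len(all_cols), len(ia)
    n_distinct = _distinct_label_permutations(n_tot, n_a)
    B = cfg.permutations
    rng = np.random.default_rng(cfg.seed)
    if B >= n_distinct:
        warnings.warn(
            f"B={B} exceeds the {n_distinct} distinct label permutations; "
            "running exhaustively"
        )
        from itertools import combinations

        assignments = [np.array(c) for c in combinations(range(n_tot), n_a)]
    else:
        assignments = [rng.permutation(n_tot)[:n_a] for _ in range(B)]
    null_abs = []
    for idx in assignments:
        sel = np.zeros(n_tot, dtype=bool)
        sel[idx] = True
        pa = all_cols[sel]
        pb = all_cols[~sel]
        d_perm, _ = _d_and_s(vals, pa, pb, s0)
        null_abs.append(np.abs(d_perm[~np.isnan(d_perm)]))
    pool = np.sort(np.concatenate(null_abs))
    n_pool = len(pool)
    obs = np.abs(d_obs)
    # count of null values >= |d_i|
    ge = n_pool - np.searchsorted(pool, obs - 1e-15, side="left")
    p = (1.0 + ge) / (1.0 + n_pool)
    p[np.isnan(d_obs)] = np.nan
    return pd.Series(p, index=m.values.index, name="p_value")


def storey_qvalues(p, lambda_: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values.

    ``pi0`` (fraction of true nulls) defaults to the fixed-lambda
    estimate ``min(1, #{p > lambda} / ((1 - lambda) m))``; q-values are
    the step-up ``q_(i) = min_{j>=i} pi0 * m * p_(j) / j``, capped at 1
    and order-preserving in p.
    """
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value list")
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv <= 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(pv)
    if pi0 is None:
        pi0 = min(1.0, np.sum(pv > lambda_) / ((1.0 - lambda_) * m))
        pi0 = max(pi0, 1.0 / m)  # keep q in (0,1]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.full_like(p, np.nan)
    idx = np.where(valid)[0]
    out[idx[order]] = q
    return out


def class_comparison(
    m: ExpressionMatrix,
    annotation: pd.DataFrame,
    contrast: Contrast | str,
    cfg: SamConfig | None = None,
) -> pd.DataFrame:
    """Full SAM-style comparison for one clinical contrast.

    Returns one row per probe with fold change (case over reference),
    group means, s_i, d_i, permutation p and Storey q, sorted by p.
    """
    if cfg is None:
        cfg = SamConfig()
    if isinstance(contrast, str):
        if contrast not in STUDY_CONTRASTS:
            raise ValueError(
                f"unknown contrast {contrast!r}; known: {sorted(STUDY_CONTRASTS)}"
            )
        contrast = STUDY_CONTRASTS[contrast]
    group_a, group_b = contrast_groups(annotation, contrast)
    group_a = [s for s in group_a if s in m.sample_ids]
    group_b = [s for s in group_b if s in m.sample_ids]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            f"contrast {contrast.name!r} needs >= 2 samples per level "
            f"(got {len(group_a)} vs {len(group_b)})"
        )
    vals = m.values.to_numpy(dtype=float)
    cols = {s: k for k, s in enumerate(m.sample_ids)}
    ia = np.array([cols[s] for s in group_a])
    ib = np.array([cols[s] for s in group_b])
    mean_a, _, _ = _group_stats(vals, ia)
    mean_b, _, _ = _group_stats(vals, ib)
    _, s = _d_and_s(vals, ia, ib, 0.0)
    s0 = cfg.s0 if cfg.s0 is not None else choose_s0(s)
    d, s = _d_and_s(vals, ia, ib, s0)
    p = permutation_pvalues(m, group_a, group_b, cfg, s0, d_obs=d)
    q = storey_qvalues(p.to_numpy())
    res = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "contrast": contrast.name,
            "fold_change": np.exp2(mean_b - mean_a),
            "mean_log2_A": mean_a,
            "mean_log2_B": mean_b,
            "s_i": s,
            "d_i": d,
            "p_value": p.to_numpy(),
            "q_value": q,
        }
    )
    return res.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def block_t_test(values: pd.DataFrame) -> tuple[float, float]:
    """Randomized-block (paired) t-test on a treatment x block table.

    Rows are the two treatments, columns the blocks.  Returns
    ``t = mean(diff) / (sd(diff)/sqrt(n_blocks))`` and the two-sided p
    from a t distribution with ``n_blocks - 1`` degrees of freedom.
    Zero-variance nonzero differences report p as the machine floor.
    """
    if values.shape[0] != 2:
        raise ValueError("exactly 2 treatments required")
    if values.shape[1] < 2:
        raise ValueError("need >= 2 blocks")
    if values.isna().any().any():
        raise ValueError("block table must be complete")
    diff = values.iloc[0] - values.iloc[1]
    n = len(diff)
    sd = float(diff.std(ddof=1))
    mean = float(diff.mean())
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), float(np.finfo(float).tiny)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def comparative_ct_fold_change(records: pd.DataFrame) -> float:
    """qPCR fold change by the comparative-CT method.

    ``records`` needs columns sample_id, condition (treated/control),
    target_ct, reference_ct.  DeltaCt = target - reference per sample;
    DeltaDeltaCt = mean treated - mean control; fold = 2^(-DDCt).
    """
    needed = {"condition", "target_ct", "reference_ct"}
    if not needed <= set(records.columns):
        raise ValueError(f"records need columns {sorted(needed)}")
    dct = records["target_ct"] - records["reference_ct"]
    by = dct.groupby(records["condition"]).mean()
    for cond in ("treated", "control"):
        if cond not in by.index:
            raise ValueError(f"missing condition {cond!r}")
    ddct = by["treated"] - by["control"]
    return float(2.0 ** (-ddct))
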