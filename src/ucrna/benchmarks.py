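"""End-to-end recovery benchmarks on synthetic cohorts.

These run the full pipeline -- catalog, spot-level simulation,
preprocessing, permutation class comparison -- against the truth table
of the generator, and report realized error rates.  They exist so that
operating characteristics (realized FDR at the q < 0.05 reporting
rule, sensitivity for planted effects) can be measured reproducibly
from a seed.
"""

from __future__ import annotations

import numpy as np

from .differential import SamConfig, class_comparison
from .preprocess import preprocess_pipeline
from .simulate import gen_expression, gen_ucr_catalog


def simulate_cohort_run(
    seed: int,
    n_ucr: int = 481,
    n_tumor: int = 57,
    n_nontumor: int = 7,
    n_effects: int = 50,
    effect_range: tuple[float, float] = (1.0, 1.5),
    permutations: int = 200,
    q_threshold: float = 0.05,
    contrast: str = "tumor_vs_normal",
):
    """Simulate one study-sized cohort with planted effects and run the
    class comparison.

    Effects are planted on ``n_effects`` distinct probes with magnitudes
    uniform in ``effect_range`` and random sign.  Returns a dict with
    the result table, the planted probe set, calls at the q threshold,
    realized false discovery fraction and sensitivity.
    """
    rng = np.random.default_rng(seed)
    _, probes = gen_ucr_catalog(n_ucr=n_ucr, seed=int(rng.integers(2**31)))
    probe_ids = [p.probe_id for p in probes]
    chosen = rng.choice(len(probe_ids), size=n_effects, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_effects)
    mags = rng.uniform(*effect_range, size=n_effects)
    effects = [
        (probe_ids[i], contrast, float(s * g))
        for i, s, g in zip(chosen, signs, mags)
    ]
    spots, ann, truth = gen_expression(
        probes,
        cohort=(n_tumor, n_nontumor),
        effects=effects,
        seed=int(rng.integers(2**31)),
    )
    matrix, dropped = preprocess_pipeline(spots)
    cfg = SamConfig(permutations=permutations, seed=int(rng.integers(2**31)))
    res = class_comparison(matrix, ann, contrast, cfg)
    planted = {pid for pid, _, _ in effects}
    called = set(res.loc[res["q_value"] < q_threshold, "probe_id"])
    false_calls = called - planted
    fdr = len(false_calls) / max(1, len(called))
    sensitivity = len(called & planted) / len(planted) if planted else float("nan")
    return {
        "result": res,
        "planted": planted,
        "called": called,
        "realized_fdr": fdr,
        "sensitivity": sensitivity,
        "n_called": len(called),
        "n_dropped": len(dropped),
        "truth": truth,
        "annotation": ann,
    }


def mean_realized_fdr(
    seeds,
    **kwargs,
) -> dict:
    """Mean realized FDR and sensitivity over a list of seeds."""
    fdrs, sens, calls = [], [], []
    for seed in seeds:
        run = simulate_cohort_run(seed, **kwargs)
        fdrs.append(run["realized_fdr"])
        sens.append(run["sensitivity"])
        calls.append(run["n_called"])
    return {
        "mean_fdr": float(np.mean(fdrs)),
        "mean_sensitivity": float(np.mean(sens)),
        "mean_calls": float(np.mean(calls)),
        "per_seed_fdr": fdrs,
        "per_seed_sensitivity": sens,
    }
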