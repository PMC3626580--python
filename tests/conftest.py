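import numpy as np
import pandas as pd
import pytest

from ucrna.containers import ExpressionMatrix, SpotTable


def make_matrix(values: np.ndarray, probe_prefix: str = "uc.", sample_prefix: str = "S"):
    """ExpressionMatrix from a plain array; NaN cells become 'missing'."""
    values = np.asarray(values, dtype=float)
    probes = [f"{probe_prefix}{i + 1}+" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j + 1:02d}" for j in range(values.shape[1])]
    return ExpressionMatrix.from_values(pd.DataFrame(values, index=probes, columns=samples))


def make_spots(slide_intensities: dict, blanks: dict | None = None) -> SpotTable:
    """SpotTable from {slide: {probe: [replicate intensities]}} plus
    optional {slide: [blank intensities]}."""
    rows = []
    for slide, probes in slide_intensities.items():
        for probe, reps in probes.items():
            for k, v in enumerate(reps, start=1):
                rows.append(
                    {
                        "slide_id": slide,
                        "spot_id": f"{slide}:{probe}:{k}",
                        "probe_id": probe,
                        "replicate_index": k,
                        "raw_intensity": float(v),
                        "flag": "ok",
                    }
                )
    for slide, vals in (blanks or {}).items():
        for k, v in enumerate(vals, start=1):
            rows.append(
                {
                    "slide_id": slide,
                    "spot_id": f"{slide}:BLANK:{k}",
                    "probe_id": "BLANK",
                    "replicate_index": 1,
                    "raw_intensity": float(v),
                    "flag": "ok",
                }
            )
    return SpotTable(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_run():
    """One small but complete simulated cohort with planted effects,
    shared across tests that only need to read its outputs."""
    from ucrna.benchmarks import simulate_cohort_run

    return simulate_cohort_run(
        seed=11,
        n_ucr=60,
        n_tumor=20,
        n_nontumor=6,
        n_effects=10,
        permutations=100,
    )
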