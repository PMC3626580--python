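"""Binary clinical contrasts over the sample annotation table.

A contrast names an annotation field and two levels; fold changes are
reported as level_b over level_a (case over reference), so that
down-regulation in the case group prints as a ratio below 1.  The
seven study contrasts cover disease status, grade, stage, spread,
race and age; Gleason sum and age are dichotomized (>=7 vs <=6,
<=60 vs >=61).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class Contrast:
    name: str
    field: str
    level_a: str  # reference
    level_b: str  # case


STUDY_CONTRASTS: dict[str, Contrast] = {
    c.name: c
    for c in [
        Contrast("tumor_vs_normal", "tissue_class", "nontumor", "tumor"),
        Contrast("gleason_high_vs_low", "gleason_group", "low", "high"),
        Contrast("stage_pt3_vs_pt2", "stage", "pT2", "pT3_4"),
        Contrast("epe_yes_vs_no", "epe", "no", "yes"),
        Contrast("svi_yes_vs_no", "svi", "no", "yes"),
        Contrast("race_aa_vs_ea", "race", "EA", "AA"),
        Contrast("age_le60_vs_ge61", "age_group", "ge61", "le60"),
    ]
}


def with_derived_fields(annotation: pd.DataFrame) -> pd.DataFrame:
    """Append the dichotomized fields used by the study contrasts."""
    ann = annotation.copy()
    if "gleason_sum" in ann:
        g = pd.to_numeric(ann["gleason_sum"], errors="coerce")
        ann["gleason_group"] = pd.Series(
            pd.NA, index=ann.index, dtype="object"
        ).mask(g >= 7, "high").mask(g <= 6, "low")
    if "age_years" in ann:
        a = pd.to_numeric(ann["age_years"], errors="coerce")
        ann["age_group"] = pd.Series(pd.NA, index=ann.index, dtype="object").mask(
            a <= 60, "le60"
        ).mask(a >= 61, "ge61")
    return ann


def contrast_groups(
    annotation: pd.DataFrame, contrast: Contrast
) -> tuple[list[str], list[str]]:
    """Sample ids in (reference, case) groups; samples with NA excluded."""
    ann = with_derived_fields(annotation)
    if contrast.field not in ann.columns:
        raise ValueError(
            f"annotation has no field {contrast.field!r}; available: "
            f"{sorted(ann.columns)}"
        )
    col = ann[contrast.field]
    a = ann.loc[col == contrast.level_a, "sample_id"].tolist()
    b = ann.loc[col == contrast.level_b, "sample_id"].tolist()
    return a, b
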