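"""Shared in-memory containers for the ucRNA pipeline.

The pipeline moves data through three representations: a spot-level
intensity table (one row per printed array spot), a summarized
probe x sample expression matrix on the log2 scale with a per-cell
mask, and a set of "truth" tables that record what a synthetic data
set actually contains (planted differential effects, planted
correlations, planted RNA:RNA interactions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: literal probe_id that marks a blank (background) spot
BLANK = "BLANK"

SPOT_COLUMNS = [
    "slide_id",
    "spot_id",
    "probe_id",
    "replicate_index",
    "raw_intensity",
    "flag",
]

SPOT_FLAGS = frozenset({"ok", "low", "filtered"})
MASK_STATES = frozenset({"present", "missing", "filtered"})


@dataclass
class UcrLocus:
    """One ultraconserved region: a genomic segment >200 bp that is
    perfectly conserved between the human, mouse and rat genomes."""

    ucr_id: str
    chrom: str
    start: int
    end: int
    ucr_class: str  # exonic | nonexonic | possibly_exonic
    host_gene: str | None
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"{self.ucr_id}: interval length {self.end - self.start} "
                f"!= sequence length {len(self.sequence)}"
            )
        if len(self.sequence) < 200:
            raise ValueError(f"{self.ucr_id}: UCRs are >200 bp by definition")


@dataclass
class Probe:
    """A strand-aware 40-mer probe for one UCR.

    Sense probes are named ``uc.N+`` and carry the genomic sequence;
    antisense probes are named ``uc.N+A`` and carry its reverse
    complement at the same offset.
    """

    probe_id: str
    ucr_id: str
    strand: str  # sense | antisense
    probe_sequence: str

    def __post_init__(self) -> None:
        if len(self.probe_sequence) != 40:
            raise ValueError(f"{self.probe_id}: probe must be a 40-mer")
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"{self.probe_id}: bad strand {self.strand!r}")


@dataclass
class SpotTable:
    """Spot-level intensities for one or more slides.

    ``data`` has columns :data:`SPOT_COLUMNS`; blank spots carry the
    literal probe_id :data:`BLANK`.  Each non-blank probe is printed in
    quadruplicate per slide; probes that violate this are flagged
    rather than silently dropped, with a note in ``warnings``.
    """

    data: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        if (self.data["raw_intensity"] < 0).any():
            bad = self.data.index[self.data["raw_intensity"] < 0][0]
            raise ValueError(f"negative raw_intensity at row {bad}")
        bad_flags = set(self.data["flag"].unique()) - SPOT_FLAGS
        if bad_flags:
            raise ValueError(f"unknown spot flags: {sorted(bad_flags)}")

    @property
    def slides(self) -> list[str]:
        return list(pd.unique(self.data["slide_id"]))

    @property
    def probe_spots(self) -> pd.DataFrame:
        return self.data[self.data["probe_id"] != BLANK]

    @property
    def blank_spots(self) -> pd.DataFrame:
        return self.data[self.data["probe_id"] == BLANK]

    def copy(self) -> "SpotTable":
        return SpotTable(self.data.copy(), list(self.warnings))


@dataclass
class ExpressionMatrix:
    """probes x samples log2 expression with a per-cell state mask.

    ``values`` is float with NaN wherever the mask is not "present";
    ``mask`` holds one of "present", "missing" (no usable replicate)
    or "filtered" (removed by a QC rule).
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValueError("values and mask must share index/columns")
        bad = set(np.unique(self.mask.to_numpy())) - MASK_STATES
        if bad:
            raise ValueError(f"unknown mask states: {sorted(bad)}")
        present = self.mask.to_numpy() == "present"
        if np.isnan(self.values.to_numpy()[present]).any():
            raise ValueError("NaN among cells marked present")

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "ExpressionMatrix":
        """Build a matrix from a plain value frame; NaN becomes 'missing'."""
        mask = pd.DataFrame(
            np.where(np.isnan(values.to_numpy(dtype=float)), "missing", "present"),
            index=values.index,
            columns=values.columns,
        )
        return cls(values.astype(float), mask)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def present(self) -> pd.DataFrame:
        return self.mask == "present"

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.mask.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.mask[list(sample_ids)])


@dataclass
class TruthTable:
    """Ground truth of a synthetic data set.

    effects:        probe_id, contrast, true_log2_effect
    correlations:   source_id, target_id, layer, true_r
    interactions:   ucrna_id, mrna_id, planted (bool)
    """

    effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["probe_id", "contrast", "true_log2_effect"]
        )
    )
    correlations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["source_id", "target_id", "layer", "true_r"]
        )
    )
    interactions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["ucrna_id", "mrna_id", "planted"])
    )


_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")
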