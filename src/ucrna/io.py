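"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (sequences, via Biopython), Vienna dot-bracket records
(structures), GPR-like tab-separated spot tables, GMT gene sets, BED
catalogs, and the YAML run configuration.  All tabular output is UTF-8
TSV with a header row; missing values are written as "NA".  Readers
reject malformed records with messages that carry a location rather
than coercing them.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import BLANK, SPOT_COLUMNS, ExpressionMatrix, SpotTable, UcrLocus

_ALPHABETS = {"DNA": set("ACGTN"), "RNA": set("ACGUN")}


# ---------------------------------------------------------------------------
# FASTA


def read_sequences(path, alphabet: str = "DNA") -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) records.

    Sequences are uppercased and converted to the requested alphabet
    (T<->U).  Duplicate ids and characters outside the alphabet (plus N)
    are rejected with the offending id / 1-based position.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"alphabet must be DNA or RNA, got {alphabet!r}")
    allowed = _ALPHABETS[alphabet]
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        seq = seq.replace("U", "T") if alphabet == "DNA" else seq.replace("T", "U")
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"record {rec.id!r}: invalid character {ch!r} at position {pos}"
                )
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_sequences(path, records) -> None:
    """Write (id, sequence) records as canonical single-line FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Vienna dot-bracket


def _check_balanced(db: str, where: str) -> None:
    depth = 0
    for ch in db:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"{where}: unbalanced brackets in {db!r}")
        elif ch != ".":
            raise ValueError(f"{where}: invalid structure character {ch!r}")
    if depth != 0:
        raise ValueError(f"{where}: unbalanced brackets in {db!r}")


def read_structures(path) -> list[tuple[str, str, str]]:
    """Read Vienna-style records: ``>id`` line, sequence line, dot-bracket
    line.  A trailing energy annotation in parentheses, as printed by
    RNAfold (e.g. ``(((...))) (-1.20)``), is permitted and ignored.

    Returns (id, sequence, dotbracket) tuples.
    """
    out: list[tuple[str, str, str]] = []
    lines = [ln.rstrip("\n") for ln in Path(path).read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record {name!r}")
        seq = lines[i + 1].strip().upper().replace("T", "U")
        db_line = lines[i + 2].strip()
        # strip a trailing "(-1.20)" style free-energy annotation
        db = db_line.split()[0]
        _check_balanced(db, f"record {name!r}")
        if len(db) != len(seq):
            raise ValueError(
                f"record {name!r}: structure length {len(db)} != sequence length {len(seq)}"
            )
        out.append((name, seq, db))
        i += 3
    return out


def write_structures(path, records) -> None:
    """Write (id, sequence, dotbracket) records in Vienna format."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq, db in records:
            fh.write(f">{name}\n{seq}\n{db}\n")


# ---------------------------------------------------------------------------
# Spot tables


def read_spot_table(path) -> SpotTable:
    """Read a GPR-like tab-separated spot table.

    Blank spots are recognized by the literal probe_id "BLANK".  A
    probe printed with other than 4 replicates on a slide is flagged
    "filtered" and a warning is recorded on the returned table; a
    negative intensity is an error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"slide_id": str, "spot_id": str, "probe_id": str})
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    neg = df.index[df["raw_intensity"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative intensity at row {neg[0] + 2}")  # 1-based + header
    table = SpotTable(df)
    probes = table.probe_spots
    counts = probes.groupby(["slide_id", "probe_id"]).size()
    bad = counts[counts != 4]
    for (slide, probe), k in bad.items():
        table.warnings.append(
            f"probe {probe!r} on slide {slide!r} has {k} replicates (expected 4); flagged"
        )
        sel = (df["slide_id"] == slide) & (df["probe_id"] == probe)
        df.loc[sel, "flag"] = "filtered"
    return table


def write_spot_table(path, table: SpotTable) -> None:
    table.data.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# GMT gene sets


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    sets: list[tuple[str, str, frozenset]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene set ids")
        for set_id, _, members in self.sets:
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (set_id TAB description TAB members...).

    Duplicate members within a set are deduplicated; a line with fewer
    than three fields is an error with its line number.
    """
    sets = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT needs >=3 tab-separated fields")
        set_id, desc, *members = fields
        sets.append((set_id, desc, frozenset(m for m in members if m)))
    return GeneSetCollection(sets)


def write_gene_sets(path, collection: GeneSetCollection) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, desc, members in collection:
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# BED catalog


def write_bed(path, loci: list[UcrLocus]) -> None:
    """Write UCR loci as 0-based half-open BED with the class in column 5's
    place-holder score slot left at 0 and strand '+'. Name is the uc.N id."""
    with open(path, "w", encoding="utf-8") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.ucr_id}\t0\t+\n")


# ---------------------------------------------------------------------------
# Expression matrices / annotations


def write_expression_matrix(path, m: ExpressionMatrix) -> None:
    m.values.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def read_expression_matrix(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id", na_values=["NA"])
    return ExpressionMatrix.from_values(df)


def write_annotation(path, ann: pd.DataFrame) -> None:
    ann.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Run-wide configuration shared by the CLI subcommands."""

    seed: int = 0
    contrasts: list[tuple[str, str, str, str]] = field(default_factory=list)
    energy_cutoff_kcal_mol: float = -10.0
    bond_fraction_cutoff: float = 0.75
    fdr_report_level: float = 0.05
    permutations: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.bond_fraction_cutoff < 1.0):
            raise ValueError("bond_fraction_cutoff must lie in (0,1)")
        if self.permutations < 1:
            raise ValueError("permutation count must be >= 1")


def read_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    contrasts = [tuple(c) for c in raw.pop("contrasts", [])]
    return RunConfig(contrasts=contrasts, **raw)
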