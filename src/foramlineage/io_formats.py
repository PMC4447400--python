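"""Readers and writers for the formats the pipeline touches.

Aligned nucleotide FASTA (via Biopython), Newick trees (hand-rolled parser
so that internal labels can follow the label-as-bootstrap convention and
errors report a character offset), and the CSV measurement-table schema
for aperture morphometrics.
"""
from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import Node, PhyloTree

# IUPAC nucleotide alphabet; gaps and N are resolved only in the
# likelihood layer (vector of ones over compatible bases).
IUPAC_CHARS = set("ACGTRYSWKMBDHVN-")


class FastaError(ValueError):
    pass


class NotAlignedError(FastaError):
    pass


class NewickParseError(ValueError):
    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One aligned nucleotide sequence with a unique taxon label."""

    taxon_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise FastaError("empty taxon_id")
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise FastaError(f"empty sequence for {self.taxon_id!r}")
        for pos, ch in enumerate(seq):
            if ch not in IUPAC_CHARS:
                raise FastaError(
                    f"illegal character {ch!r} at position {pos + 1} "
                    f"in sequence {self.taxon_id!r}"
                )
        self.sequence = seq


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with unique taxon labels."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise NotAlignedError("alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise NotAlignedError(
                f"sequences are not aligned: lengths {sorted(lengths)}"
            )
        ids = [r.taxon_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FastaError(f"duplicate taxon_id: {dupes}")

    @property
    def n_sites(self) -> int:
        return len(self.records[0].sequence)

    @property
    def taxon_ids(self) -> list[str]:
        return [r.taxon_id for r in self.records]

    def subset(self, taxa: list[str]) -> "Alignment":
        by_id = {r.taxon_id: r for r in self.records}
        missing = [t for t in taxa if t not in by_id]
        if missing:
            raise KeyError(f"taxa not in alignment: {missing}")
        return Alignment([by_id[t] for t in taxa])


def read_fasta(path: Union[str, os.PathLike, io.TextIOBase]) -> Alignment:
    """Read an aligned FASTA file; U is normalized to T, case to upper."""
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    return Alignment(records)


def write_fasta(aln: Alignment, path: Union[str, os.PathLike, io.TextIOBase]) -> None:
    """Write an alignment; read_fasta(write_fasta(aln)) round-trips."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.taxon_id, description=r.description)
        for r in aln.records
    ]
    SeqIO.write(seqs, path, "fasta")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string.

    Numeric internal-node labels are interpreted as bootstrap supports in
    [0, 100]; non-numeric labels are kept as names.  Missing branch
    lengths are stored as None, never as zero.
    """
    s = text.strip()
    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(msg, pos)

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def read_label() -> str:
        nonlocal pos
        if peek() == "'":
            end = s.find("'", pos + 1)
            if end < 0:
                raise error("unterminated quoted label")
            label = s[pos + 1:end]
            pos = end + 1
            return label
        start = pos
        while pos < len(s) and s[pos] not in "(),:;[]":
            pos += 1
        return s[start:pos].strip()

    def read_length() -> Optional[float]:
        nonlocal pos
        if peek() != ":":
            return None
        pos += 1
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        try:
            return float(s[start:pos])
        except ValueError:
            raise error(f"bad branch length {s[start:pos]!r}") from None

    def read_clade() -> Node:
        nonlocal pos
        node = Node()
        if peek() == "(":
            pos += 1
            node.add_child(read_clade())
            while peek() == ",":
                pos += 1
                node.add_child(read_clade())
            if peek() != ")":
                raise error("expected ')' or ','")
            pos += 1
            label = read_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            label = read_label()
            if not label:
                raise error("expected a taxon label")
            node.name = label
        node.length = read_length()
        return node

    if not s:
        raise NewickParseError("empty Newick string", 0)
    root = read_clade()
    if peek() != ";":
        raise error("expected ';'")
    pos += 1
    if pos < len(s):
        raise error("trailing characters after ';'")
    return PhyloTree(root)


def serialize_newick(tree: PhyloTree, canonical: bool = True) -> str:
    """Serialize to Newick; supports become internal labels.

    With ``canonical=True`` children are ordered by their smallest
    descendant leaf label, so isomorphic trees serialize identically.
    """

    def min_leaf(node: Node) -> str:
        if node.is_leaf:
            return node.name or ""
        return min(min_leaf(c) for c in node.children)

    def fmt(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            children = node.children
            if canonical:
                children = sorted(children, key=min_leaf)
            inner = ",".join(fmt(c, False) for c in children)
            label = ""
            if node.support is not None:
                label = format(node.support, "g")
            elif node.name:
                label = node.name
            body = f"({inner}){label}"
        if not is_root and node.length is not None:
            body += f":{node.length:.10g}"
        return body

    return fmt(tree.root, True) + ";"


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = [
    "specimen_id", "sample_id", "zone", "morphospecies",
    "width_um", "height_um", "angle1_deg", "angle2_deg",
]
OPTIONAL_COLUMNS = ["lineage"]
NUMERIC_COLUMNS = ["width_um", "height_um", "angle1_deg", "angle2_deg"]


@dataclass
class MeasurementTable:
    """Validated per-specimen aperture geometry.

    ``data`` holds accepted rows; ``rejected`` holds rejected rows with a
    ``reason`` column.  accepted + rejected = input row count.
    """

    data: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=REQUIRED_COLUMNS + ["reason"])
    )

    def __len__(self) -> int:
        return len(self.data)


def _coerce_numeric(col: pd.Series) -> pd.Series:
    """Numeric conversion tolerating both '.' and ',' decimal separators."""
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float)
    cleaned = col.astype(str).str.strip().str.replace(",", ".", regex=False)
    return pd.to_numeric(cleaned, errors="coerce")


def validate_measurements(df: pd.DataFrame) -> MeasurementTable:
    """Validate a raw measurement frame against the schema invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.copy()
    if "lineage" not in df.columns:
        df["lineage"] = pd.NA
    for col in NUMERIC_COLUMNS:
        df[col] = _coerce_numeric(df[col])

    reasons = pd.Series([""] * len(df), index=df.index)
    for col in NUMERIC_COLUMNS:
        bad = df[col].isna()
        reasons[bad & (reasons == "")] = f"non-numeric {col}"
    for col in ("width_um", "height_um"):
        what = col.split("_")[0]
        bad = df[col].notna() & (df[col] <= 0)
        reasons[bad & (reasons == "")] = f"non-positive {what}"
    for col in ("angle1_deg", "angle2_deg"):
        bad = df[col].notna() & ~((df[col] > 0) & (df[col] < 180))
        reasons[bad & (reasons == "")] = f"{col} outside (0, 180)"

    ok = reasons == ""
    accepted = df[ok].reset_index(drop=True)
    rejected = df[~ok].copy()
    rejected["reason"] = reasons[~ok]
    return MeasurementTable(accepted, rejected.reset_index(drop=True))


def read_measurement_table(path: Union[str, os.PathLike]) -> MeasurementTable:
    """Read and validate a morphometric measurement CSV."""
    df = pd.read_csv(path)
    return validate_measurements(df)


def write_measurement_table(table: MeasurementTable, path: Union[str, os.PathLike]) -> None:
    table.data.to_csv(path, index=False)
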