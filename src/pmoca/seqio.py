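"""Sequence, annotation and alignment I/O for operon records.

The working unit is the :class:`OperonRecord`: one nucleotide sequence
carrying gene intervals (pmoC/pmoA/pmoB), a lineage label and a copy
index — genomes with multiple operon copies contribute one record per
copy.  Coordinates are 1-based inclusive throughout, following the
community convention behind primer names like pmoC374 ("nucleotide
position 374 within the gene").

FASTA parsing/writing delegates to Bio.SeqIO; annotation and group
tables are plain 5- and 2-column TSV read with pandas.  Minus-strand
annotations are reverse-complemented into plus-strand working copies at
load time so that all window arithmetic runs on the plus strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import IUPAC_SETS, InvalidSymbolError, normalize

__all__ = [
    "GeneInterval",
    "OperonRecord",
    "AlignmentSet",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "read_groups",
    "load_records",
    "intergenic_lengths",
    "translate",
]


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive gene interval on a record."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval ({self.start}, {self.end}): need 1 <= start <= end")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class OperonRecord:
    """One nucleotide sequence plus gene intervals, lineage label, copy index."""

    id: str
    sequence: str
    genes: dict[str, GeneInterval] = field(default_factory=dict)
    group: str = "unassigned"
    copy_index: int = 1

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence, context=f"record {self.id}")
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ValueError(f"record {self.id}: empty sequence")
        for gene, iv in self.genes.items():
            if iv.end > n:
                raise ValueError(
                    f"record {self.id}: {gene} interval ({iv.start}, {iv.end}) "
                    f"exceeds sequence length {n}"
                )
        c, a = self.genes.get("pmoC"), self.genes.get("pmoA")
        if c and a and c.strand == "+" and a.strand == "+" and not c.end < a.start:
            raise ValueError(
                f"record {self.id}: operon order violated, pmoC end {c.end} "
                f">= pmoA start {a.start}"
            )

    def gene_region(self, gene: str) -> str:
        """Plus-strand subsequence of an annotated gene."""
        iv = self.genes[gene]
        return self.sequence[iv.start - 1 : iv.end]

    def intergenic_length(self, left: str = "pmoC", right: str = "pmoA") -> int:
        """Bases strictly between two annotated genes."""
        return self.genes[right].start - self.genes[left].end - 1

    def reverse_complement(self) -> "OperonRecord":
        """Record on the opposite strand with intervals remapped."""
        n = len(self.sequence)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        rc = "".join(comp[b] for b in reversed(self.sequence))
        genes = {
            g: GeneInterval(n - iv.end + 1, n - iv.start + 1, "+" if iv.strand == "-" else "-")
            for g, iv in self.genes.items()
        }
        return OperonRecord(self.id, rc, genes, self.group, self.copy_index)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[tuple[str, str]]:
    """Read FASTA as ``[(id, normalized sequence), ...]`` preserving order.

    Duplicate identifiers, empty sequences and characters outside the
    IUPAC alphabet (plus ``-``/``.`` when ``allow_gaps``) are rejected
    with the offending record named.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        try:
            seq = normalize(raw, context=f"record {rec.id}", allow_gaps=allow_gaps)
        except InvalidSymbolError as e:
            raise ValueError(f"{path}: record {rec.id!r}: {e}") from e
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, wrap: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Tables


def read_annotations(path: str | Path) -> dict[str, dict[str, GeneInterval]]:
    """Read the gene-annotation TSV: record_id, gene, start, end, strand.

    Lines starting with '#' are comments.  Same-name duplicate genes on a
    record and invalid intervals are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"record_id": str, "gene": str})
    required = {"record_id", "gene", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation TSV needs columns {sorted(required)}")
    ann: dict[str, dict[str, GeneInterval]] = {}
    for row in df.itertuples(index=False):
        per = ann.setdefault(row.record_id, {})
        if row.gene in per:
            raise ValueError(f"{path}: duplicate gene {row.gene!r} for record {row.record_id!r}")
        per[row.gene] = GeneInterval(int(row.start), int(row.end), str(row.strand))
    return ann


def read_groups(path: str | Path) -> dict[str, str]:
    """Read the group TSV: record_id, group."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"record_id", "group"}.issubset(df.columns):
        raise ValueError(f"{path}: group TSV needs columns ['record_id', 'group']")
    return dict(zip(df["record_id"], df["group"]))


def load_records(
    fasta_path: str | Path,
    annotations_path: str | Path | None = None,
    groups_path: str | Path | None = None,
) -> list[OperonRecord]:
    """Assemble OperonRecords from FASTA plus optional annotation/group TSVs.

    Records whose annotated genes all sit on the minus strand are
    reverse-complemented into plus-strand working copies; a mixed-strand
    annotation is rejected.  Annotation rows referring to unknown record
    ids are reported.
    """
    seqs = read_fasta(fasta_path)
    ann = read_annotations(annotations_path) if annotations_path else {}
    groups = read_groups(groups_path) if groups_path else {}
    known = {rid for rid, _ in seqs}
    unknown = sorted(set(ann) - known)
    if unknown:
        raise ValueError(f"annotations refer to unknown record ids: {unknown[:5]}")
    records = []
    for rid, seq in seqs:
        genes = ann.get(rid, {})
        strands = {iv.strand for iv in genes.values()}
        rec = OperonRecord(rid, seq, dict(genes), groups.get(rid, "unassigned"))
        if strands == {"-"}:
            rec = rec.reverse_complement()
        elif len(strands) > 1:
            raise ValueError(f"record {rid}: mixed-strand gene annotations are not supported")
        records.append(rec)
    return records


def intergenic_lengths(
    records: Sequence[OperonRecord], left: str = "pmoC", right: str = "pmoA"
) -> pd.DataFrame:
    """Per-record intergenic spacer lengths between two annotated genes.

    Records missing either annotation are skipped.  Returns a DataFrame
    with columns record_id, group, length; summary statistics via
    ``df["length"].mean()`` etc.  Order-invariant under FASTA reordering
    (rows sorted by record id).
    """
    rows = [
        (r.id, r.group, r.intergenic_length(left, right))
        for r in records
        if left in r.genes and right in r.genes
    ]
    df = pd.DataFrame(rows, columns=["record_id", "group", "length"])
    return df.sort_values("record_id", ignore_index=True)


# ---------------------------------------------------------------------------
# Alignment


class AlignmentSet:
    """A gapped alignment with column <-> ungapped-coordinate maps.

    ``col_map(rid)`` gives, per alignment column (0-based), the 0-based
    ungapped position in the row's sequence, or -1 at a gap.  The map is
    strictly increasing over non-gap columns, so degapping a row
    reproduces the record's sequence over the aligned region.
    """

    def __init__(self, rows: Mapping[str, str]):
        if not rows:
            raise ValueError("alignment has no rows")
        self.rows: dict[str, str] = {
            rid: normalize(s, context=f"aligned row {rid}", allow_gaps=True).replace(".", "-")
            for rid, s in rows.items()
        }
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"aligned rows have unequal lengths: {sorted(lengths)}")
        self.n_columns = lengths.pop()
        self._col_maps: dict[str, np.ndarray] = {}
        for rid, s in self.rows.items():
            arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            is_base = arr != ord("-")
            cm = np.cumsum(is_base) - 1
            cm[~is_base] = -1
            self._col_maps[rid] = cm

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentSet":
        return cls(dict(read_fasta(path, allow_gaps=True)))

    def col_map(self, rid: str) -> np.ndarray:
        return self._col_maps[rid]

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace("-", "")

    def window(self, rid: str, start_col: int, width: int) -> str:
        """Gapped slice of one row; ``start_col`` 0-based."""
        return self.rows[rid][start_col : start_col + width]

    def ungapped_position(self, rid: str, col: int) -> int:
        """0-based ungapped position at column ``col``; -1 at a gap."""
        return int(self._col_maps[rid][col])


# ---------------------------------------------------------------------------
# Translation

_STANDARD = standard_dna_table.forward_table


def _codon_residue(codon: str) -> str:
    """Residue of a possibly degenerate codon; 'X' unless all expansions agree."""
    if all(c in "ACGT" for c in codon):
        return _STANDARD.get(codon, "*")
    residues = {
        _STANDARD.get("".join(combo), "*")
        for combo in itertools.product(*(sorted(IUPAC_SETS[c]) for c in codon))
    }
    return residues.pop() if len(residues) == 1 else "X"


def translate(sequence: str, frame: int = 0) -> str:
    """Translate a (possibly degenerate) region with the standard code.

    ``frame`` is the 0-based offset into the region; the trailing partial
    codon is dropped.  A degenerate codon translates to its residue when
    every expansion agrees, else to 'X'; stop codons render as '*'.
    """
    seq = normalize(sequence, context="translation input")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    coding = seq[frame:]
    if len(coding) < 3:
        raise ValueError("region shorter than one codon after frame offset")
    aa = [_codon_residue(coding[i : i + 3]) for i in range(0, len(coding) - len(coding) % 3, 3)]
    return "".join(aa)


def records_to_seqrecords(records: Iterable[OperonRecord]) -> list[SeqRecord]:
    """Biopython view of records, for interop with SeqIO consumers."""
    return [SeqRecord(Seq(r.sequence), id=r.id, description=r.group) for r in records]
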