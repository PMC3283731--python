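"""Alignment data model, FASTA/NEXUS I/O, and composition summaries.

The central object is :class:`Alignment`: an ordered, equal-length set of
DNA sequence records over the IUPAC alphabet with ``-`` as the indel symbol,
tagged with the treatment stage it has been through (T1 = as aligned,
T2 = terminal gaps relabelled ``N``, T3 = ambiguous columns removed).
All reported column coordinates are 1-based inclusive; internal array
indexing is 0-based.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: IUPAC nucleotide codes mapped to the unambiguous bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAP = "-"
BASES = ("A", "C", "G", "T")
AMBIGUITY_CODES = tuple(c for c in IUPAC_CODES if c not in BASES)
ALPHABET = frozenset(IUPAC_CODES) | {GAP}

VALID_TREATMENTS = ("T1", "T2", "T3")


class AlignmentError(ValueError):
    """Structural problem with an alignment (ragged records, bad symbols)."""


def _canonicalize(residues: str, seq_id: str) -> str:
    """Uppercase, map U->T, and validate against the alignment alphabet."""
    out = residues.upper().replace("U", "T")
    if not out:
        raise AlignmentError(f"record {seq_id!r} is empty")
    for pos, sym in enumerate(out, start=1):
        if sym not in ALPHABET:
            raise AlignmentError(
                f"record {seq_id!r} has non-alphabet symbol {sym!r} at column {pos}"
            )
    return out


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned DNA sequence: a unique id and its residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _canonicalize(self.residues, self.id))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """Equal-length sequence records plus a treatment tag (T1/T2/T3)."""

    records: tuple[SequenceRecord, ...]
    treatment: str = "T1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise AlignmentError("alignment has no records")
        if self.treatment not in VALID_TREATMENTS:
            raise AlignmentError(f"unknown treatment tag {self.treatment!r}")
        ref_len = len(self.records[0])
        bad = [r.id for r in self.records if len(r) != ref_len]
        if bad:
            raise AlignmentError(
                f"records not all of length {ref_len}: {', '.join(bad)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate record ids: {', '.join(dupes)}")

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    @property
    def column_count(self) -> int:
        return len(self.records[0])

    def column(self, index: int) -> list[str]:
        """Symbols of 0-based column *index*, top to bottom."""
        return [r.residues[index] for r in self.records]

    def to_array(self) -> np.ndarray:
        """(n_records, n_columns) array of single-character strings."""
        return np.array([list(r.residues) for r in self.records], dtype="U1")

    def with_treatment(self, tag: str) -> "Alignment":
        return Alignment(self.records, treatment=tag)


@dataclass(frozen=True)
class CompositionSummary:
    """Cell-level composition percentages plus gap-column fraction."""

    base_frequencies: dict[str, float]
    ambiguity_frequency_total: float
    ambiguity_codes_present: tuple[str, ...]
    gap_frequency: float
    gap_containing_column_fraction: float


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".nex", ".nexus", ".nxs"):
        return "nexus"
    return "fasta"


def read_alignment(path: str | os.PathLike, fmt: str | None = None) -> Alignment:
    """Read a FASTA or NEXUS alignment into a validated :class:`Alignment`.

    NEXUS ``?`` (missing) maps to ``N`` and ``.`` to ``-``; lowercase input
    and RNA ``U`` are canonicalized. The treatment tag defaults to T1.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "fasta":
        bio_records = list(SeqIO.parse(str(path), "fasta"))
    elif fmt == "nexus":
        bio_records = list(AlignIO.read(str(path), "nexus"))
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    if not bio_records:
        raise AlignmentError(f"no sequences found in {path}")
    records = []
    for rec in bio_records:
        residues = str(rec.seq)
        if fmt == "nexus":
            residues = residues.replace("?", "N").replace(".", "-")
        records.append(SequenceRecord(rec.id, residues))
    return Alignment(tuple(records), treatment="T1")


def write_alignment(
    aln: Alignment, path: str | os.PathLike, fmt: str | None = None
) -> str:
    """Write *aln* to FASTA or NEXUS; round-trips ids and residues exactly."""
    fmt = _infer_format(path, fmt)
    bio_records = [
        _BioSeqRecord(
            Seq(r.residues),
            id=r.id,
            description="",
            annotations={"molecule_type": "DNA"},
        )
        for r in aln
    ]
    if fmt == "fasta":
        SeqIO.write(bio_records, str(path), "fasta")
    elif fmt == "nexus":
        msa = MultipleSeqAlignment(bio_records)
        AlignIO.write(msa, str(path), "nexus")
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    return str(path)


def composition_summary(aln: Alignment) -> CompositionSummary:
    """Percent composition over all matrix cells, Table-style.

    Base, ambiguity and gap percentages are computed over every cell of the
    record x column matrix and sum to 100; the gap-containing column
    fraction is the percentage of columns holding at least one ``-``.
    """
    arr = aln.to_array()
    n_cells = arr.size
    base_freqs = {b: 100.0 * np.count_nonzero(arr == b) / n_cells for b in BASES}
    amb_present = []
    amb_total = 0.0
    for code in AMBIGUITY_CODES:
        count = np.count_nonzero(arr == code)
        if count:
            amb_present.append(code)
            amb_total += 100.0 * count / n_cells
    gap_freq = 100.0 * np.count_nonzero(arr == GAP) / n_cells
    gap_cols = np.count_nonzero((arr == GAP).any(axis=0))
    return CompositionSummary(
        base_frequencies=base_freqs,
        ambiguity_frequency_total=amb_total,
        ambiguity_codes_present=tuple(sorted(amb_present)),
        gap_frequency=gap_freq,
        gap_containing_column_fraction=100.0 * gap_cols / aln.column_count,
    )
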