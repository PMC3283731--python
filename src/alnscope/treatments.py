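"""Alignment treatments: terminal-gap relabelling (T2) and column exclusion (T3).

Environmental amplicon alignments typically carry leading/trailing overhangs
(sequences of unequal read length) and internal blocks whose positional
homology is doubtful. T2 relabels every terminal ``-`` run as ``N`` so that
downstream statistics treat overhangs as missing data rather than asserted
indels; T3 additionally deletes a user-supplied (or auto-detected) set of
ambiguously alignable columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from alnscope.alignment import Alignment, AlignmentError, SequenceRecord

_LEAD = re.compile(r"^-+")
_TRAIL = re.compile(r"-+$")


@dataclass(frozen=True)
class ColumnMask:
    """Non-overlapping 1-based inclusive column intervals to exclude."""

    excluded_ranges: tuple[tuple[int, int], ...]
    source: str = "user"

    def __post_init__(self) -> None:
        norm = _normalize_ranges(self.excluded_ranges)
        object.__setattr__(self, "excluded_ranges", norm)

    @property
    def excluded_count(self) -> int:
        return sum(end - start + 1 for start, end in self.excluded_ranges)

    def excluded_indices(self, column_count: int) -> np.ndarray:
        """0-based indices of excluded columns; validates bounds."""
        idx: list[int] = []
        for start, end in self.excluded_ranges:
            if start < 1 or end > column_count:
                raise ValueError(
                    f"mask interval {start}-{end} outside alignment "
                    f"columns 1-{column_count}"
                )
            idx.extend(range(start - 1, end))
        return np.array(idx, dtype=int)

    @classmethod
    def from_tsv(cls, path: str, source: str = "user") -> "ColumnMask":
        ranges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                start, end = line.split("\t")[:2]
                ranges.append((int(start), int(end)))
        return cls(tuple(ranges), source=source)

    def to_tsv(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.write("# start\tend (1-based inclusive)\n")
            for start, end in self.excluded_ranges:
                fh.write(f"{start}\t{end}\n")
        return path


def _normalize_ranges(
    ranges: tuple[tuple[int, int], ...]
) -> tuple[tuple[int, int], ...]:
    """Sort and merge overlapping/adjacent intervals."""
    checked = []
    for start, end in ranges:
        if end < start:
            raise ValueError(f"interval {start}-{end} has end < start")
        if start < 1:
            raise ValueError(f"interval {start}-{end} not 1-based")
        checked.append((int(start), int(end)))
    checked.sort()
    merged: list[list[int]] = []
    for start, end in checked:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def apply_t2(aln: Alignment) -> Alignment:
    """Relabel every leading and trailing ``-`` run as ``N`` (treatment T2).

    Internal gaps are untouched, the column count is unchanged, and the
    operation is idempotent. A record that is entirely gaps becomes
    entirely ``N``.
    """
    records = []
    for rec in aln:
        residues = _LEAD.sub(lambda m: "N" * len(m.group()), rec.residues)
        residues = _TRAIL.sub(lambda m: "N" * len(m.group()), residues)
        records.append(SequenceRecord(rec.id, residues))
    return Alignment(tuple(records), treatment="T2")


def apply_t3(aln: Alignment, mask: ColumnMask) -> Alignment:
    """Apply T2 if needed, then delete the masked columns (treatment T3)."""
    if aln.treatment == "T1":
        aln = apply_t2(aln)
    excluded = set(mask.excluded_indices(aln.column_count).tolist())
    keep = [i for i in range(aln.column_count) if i not in excluded]
    if not keep:
        raise AlignmentError("mask excludes every column")
    records = tuple(
        SequenceRecord(rec.id, "".join(rec.residues[i] for i in keep)) for rec in aln
    )
    return Alignment(records, treatment="T3")


def detect_ambiguous_columns(
    aln: Alignment,
    gap_threshold: float = 0.5,
    entropy_threshold: float = 1.5,
    window: int = 5,
) -> ColumnMask:
    """Automatic surrogate for manual exclusion of ambiguously alignable areas.

    A column is flagged when the windowed (centred moving-average) mean gap
    fraction exceeds *gap_threshold* or the windowed mean column entropy
    exceeds *entropy_threshold* (nats). Consecutive flagged columns are
    merged into intervals. This is a stand-in for expert curation: it finds
    gap-rich, high-entropy blocks but knows nothing about homology.
    """
    from alnscope.entropy import entropy_profile  # local import: avoid cycle

    if window < 1:
        raise ValueError("window must be >= 1")
    if aln.column_count < window:
        raise ValueError(
            f"window {window} exceeds column count {aln.column_count}"
        )
    arr = aln.to_array()
    gap_fraction = (arr == "-").mean(axis=0)
    entropies = entropy_profile(aln).entropies
    kernel = np.ones(window) / window
    # centred moving average; edges shrink to the available neighbourhood
    def _smooth(values: np.ndarray) -> np.ndarray:
        padded = np.convolve(values, kernel, mode="same")
        counts = np.convolve(np.ones_like(values), kernel, mode="same")
        return padded / counts

    flagged = (_smooth(gap_fraction) > gap_threshold) | (
        _smooth(entropies) > entropy_threshold
    )
    ranges = []
    start = None
    for i, flag in enumerate(flagged):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            ranges.append((start + 1, i))
            start = None
    if start is not None:
        ranges.append((start + 1, len(flagged)))
    return ColumnMask(tuple(ranges), source="auto")
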