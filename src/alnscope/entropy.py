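"""Gap- and ambiguity-aware Shannon entropy of alignment columns.

Each alignment cell distributes one unit of weight over the five character
states A, C, G, T and E, where E is the "real indel" state. An unambiguous
base puts its whole weight on that base. A gap (``-``) or an ``N`` could in
reality be any of the four bases or a true indel, so it contributes 1/5 to
each of the five states. Any other IUPAC ambiguity code splits its weight
equally over its constituent bases (Y -> C/2 + T/2, B -> C/3 + G/3 + T/3,
and so on). Column entropy is then the ordinary Shannon entropy, in nats,
of the resulting five-state frequency vector, with non-occurring states
omitted (0 * ln 0 := 0), which makes the maximum attainable entropy differ
from column to column.

The cumulative entropy H of an alignment is the sum of the column
entropies; the relative heterogeneity h = H / H_max expresses it as a
fraction of the cumulative maximum attainable entropy. h = 0 means every
column carries a single state (no phylogenetic information at all); h = 1
means every occurring state is equally frequent in every column (no column
resolves any partition). Both are reported separately for gap-free (H_f,
h_f) and gap-containing (H_g, h_g) columns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from alnscope.alignment import BASES, GAP, IUPAC_CODES, Alignment

#: Fixed state order for frequency vectors: the four bases plus the
#: real-indel state E.
STATES = ("A", "C", "G", "T", "E")

LN5 = math.log(5.0)


def _build_contributions(n_states: int) -> dict[str, np.ndarray]:
    table: dict[str, np.ndarray] = {}
    for code, bases in IUPAC_CODES.items():
        vec = np.zeros(5)
        if code == "N":
            continue
        share = 1.0 / len(bases)
        for b in bases:
            vec[STATES.index(b)] = share
        table[code] = vec
    table[GAP] = np.full(5, 0.2)
    if n_states == 5:
        table["N"] = np.full(5, 0.2)
    elif n_states == 4:
        table["N"] = np.array([0.25, 0.25, 0.25, 0.25, 0.0])
    else:
        raise ValueError("n_states must be 4 or 5")
    return table


_CONTRIB_5 = _build_contributions(5)
_CONTRIB_4 = _build_contributions(4)


@dataclass(frozen=True)
class StateFrequencies:
    """Five-state frequency vector (A, C, G, T, E) for one column."""

    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {total}, expected 1")

    def as_vector(self) -> np.ndarray:
        return np.array([self.frequencies[s] for s in STATES])

    @property
    def occurring_states(self) -> int:
        return sum(1 for v in self.frequencies.values() if v > 0)


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column entropies plus the bookkeeping needed for summaries.

    ``state_frequencies`` is an (n_columns, 5) array over STATES;
    ``gap_flag`` marks columns containing at least one ``-``;
    ``gap_fraction`` is the per-column fraction of ``-`` cells.
    """

    entropies: np.ndarray
    gap_flag: np.ndarray
    gap_fraction: np.ndarray
    state_frequencies: np.ndarray

    @property
    def column_count(self) -> int:
        return len(self.entropies)


@dataclass(frozen=True)
class HeterogeneitySummary:
    """Cumulative entropy and relative heterogeneity, split by gap content."""

    H_total: float
    H_f: float
    H_g: float
    h: float
    h_f: float
    h_g: float
    mean_entropy: float
    median_entropy: float
    positions_H_pos_gapfree: int
    positions_H_zero_gapfree: int
    h_max_mode: str


@dataclass(frozen=True)
class EntropyRun:
    """Maximal run of consecutive columns above an entropy threshold."""

    start: int  # 1-based inclusive
    end: int
    mean_gap_frequency: float  # percent

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def column_state_frequencies(
    column: list[str] | str, n_states: int = 5
) -> StateFrequencies:
    """Distribute each cell's unit weight over the five states and average.

    ``n_states=5`` (default) treats ``N`` like a gap (1/5 to each state,
    including the real-indel state E); ``n_states=4`` spreads ``N`` over
    the four bases only, for sensitivity analysis.
    """
    if len(column) == 0:
        raise ValueError("empty column")
    table = _CONTRIB_5 if n_states == 5 else _CONTRIB_4
    total = np.zeros(5)
    for sym in column:
        try:
            total += table[sym]
        except KeyError:
            raise ValueError(f"unknown symbol {sym!r} in column") from None
    total /= len(column)
    return StateFrequencies(dict(zip(STATES, total.tolist())))


def column_entropy(freqs: StateFrequencies) -> float:
    """Shannon entropy, in nats, of a five-state frequency vector.

    Non-occurring states are skipped rather than contributing 0*ln 0.
    """
    vec = freqs.as_vector()
    vec = vec[vec > 0]
    return float(-np.sum(vec * np.log(vec)))


def entropy_profile(aln: Alignment, n_states: int = 5) -> EntropyProfile:
    """Column-by-column entropy landscape of an alignment."""
    table = _CONTRIB_5 if n_states == 5 else _CONTRIB_4
    arr = aln.to_array()
    n_rows, n_cols = arr.shape
    freqs = np.zeros((n_cols, 5))
    for sym, vec in table.items():
        counts = (arr == sym).sum(axis=0)
        freqs += counts[:, None] * vec[None, :]
    freqs /= n_rows
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
    entropies = -terms.sum(axis=1)
    entropies[entropies < 0] = 0.0  # guard against -0.0 / rounding
    gap_fraction = (arr == GAP).mean(axis=0)
    return EntropyProfile(
        entropies=entropies,
        gap_flag=gap_fraction > 0,
        gap_fraction=gap_fraction,
        state_frequencies=freqs,
    )


def _h_ratio(H: float, H_max: float) -> float:
    if H_max == 0.0:
        return 0.0
    return H / H_max


def heterogeneity_summary(
    profile: EntropyProfile, h_max_mode: str = "occurring_states"
) -> HeterogeneitySummary:
    """Cumulative entropy H, its gap-free/gap-containing split, and h ratios.

    ``occurring_states`` (default) takes each column's maximum attainable
    entropy as ln k_i, where k_i is the number of states with nonzero
    frequency there (single-state columns contribute nothing to numerator
    or denominator). ``uniform5`` uses a fixed ln 5 per column.
    """
    if profile.column_count == 0:
        raise ValueError("empty entropy profile")
    if h_max_mode not in ("occurring_states", "uniform5"):
        raise ValueError(f"unknown h_max_mode {h_max_mode!r}")
    H_i = profile.entropies
    k_i = (profile.state_frequencies > 0).sum(axis=1)
    if h_max_mode == "occurring_states":
        H_max_i = np.log(k_i.astype(float))
    else:
        H_max_i = np.full(profile.column_count, LN5)
    gapped = profile.gap_flag
    H_f = float(H_i[~gapped].sum())
    H_g = float(H_i[gapped].sum())
    H_total = H_f + H_g  # exact partition by construction
    denom_total = float(H_max_i.sum())
    denom_f = float(H_max_i[~gapped].sum())
    denom_g = float(H_max_i[gapped].sum())
    if denom_total == 0.0:
        warnings.warn(
            "alignment is fully conserved; relative heterogeneity defined as 0",
            stacklevel=2,
        )
    gapfree_H = H_i[~gapped]
    return HeterogeneitySummary(
        H_total=H_total,
        H_f=H_f,
        H_g=H_g,
        h=_h_ratio(H_total, denom_total),
        h_f=_h_ratio(H_f, denom_f),
        h_g=_h_ratio(H_g, denom_g),
        mean_entropy=float(H_i.mean()),
        median_entropy=float(np.median(H_i)),
        positions_H_pos_gapfree=int((gapfree_H > 0).sum()),
        positions_H_zero_gapfree=int((gapfree_H == 0).sum()),
        h_max_mode=h_max_mode,
    )


def high_entropy_runs(
    profile: EntropyProfile, threshold: float = 1.5, min_length: int = 2
) -> list[EntropyRun]:
    """Maximal runs of consecutive columns with entropy strictly above
    *threshold*, keeping only runs of at least *min_length* columns.

    Each run is annotated with its mean gap frequency (percent), since in
    practice the longest high-entropy runs coincide with gap-rich blocks.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    above = profile.entropies > threshold
    runs: list[EntropyRun] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_length:
                runs.append(_make_run(profile, start, i - 1))
            start = None
    if start is not None and profile.column_count - start >= min_length:
        runs.append(_make_run(profile, start, profile.column_count - 1))
    return runs


def _make_run(profile: EntropyProfile, start0: int, end0: int) -> EntropyRun:
    mean_gap = float(profile.gap_fraction[start0 : end0 + 1].mean()) * 100.0
    return EntropyRun(start=start0 + 1, end=end0 + 1, mean_gap_frequency=mean_gap)
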