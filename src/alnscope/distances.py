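"""Kimura-2-parameter distances and substitution-saturation profiles.

For each sequence pair, comparable sites are those where both sequences
carry an unambiguous base (gaps, N and other IUPAC ambiguity codes are
excluded). Differences are split into transitions (purine<->purine,
pyrimidine<->pyrimidine) and transversions; with transition proportion P
and transversion proportion Q the K2P distance is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

The distance is undefined once either logarithm argument reaches zero
(substitution saturation); such pairs are recorded, never silently
dropped. The saturation profile plots per-pair transition and transversion
counts against d, DAMBE-style: saturation is diagnosed where the binned
mean transversion count overtakes the transition count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from alnscope.alignment import Alignment, SequenceRecord
from alnscope.otu import usable_columns

# base codes: A=0, G=1 (purines); C=2, T=3 (pyrimidines); other=255.
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}


class UndefinedDistanceError(ValueError):
    """K2P correction inapplicable (logarithm argument <= 0)."""


@dataclass(frozen=True)
class PairSubstitutionSummary:
    transitions_s: int
    transversions_v: int
    compared_sites: int

    @property
    def P(self) -> float:
        return self.transitions_s / self.compared_sites

    @property
    def Q(self) -> float:
        return self.transversions_v / self.compared_sites


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix; saturated pairs are flagged as NaN."""

    labels: tuple[str, ...]
    d: np.ndarray
    undefined_pairs: frozenset[tuple[str, str]]

    def distance(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass(frozen=True)
class SaturationProfile:
    """Per-pair (d, s, v) records plus binned means/SDs versus distance."""

    pair_records: np.ndarray  # columns: d, s, v, P, Q
    bin_centers: np.ndarray
    mean_s: np.ndarray
    mean_v: np.ndarray
    sd_s: np.ndarray
    sd_v: np.ndarray
    crossover_distance: float | None


def _encode(aln: Alignment) -> np.ndarray:
    arr = aln.to_array()
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for sym, code in _CODE.items():
        codes[arr == sym] = code
    return codes


def pairwise_substitution_summary(
    a: SequenceRecord,
    b: SequenceRecord,
    site_policy: str = "pairwise_deletion",
    global_columns: np.ndarray | None = None,
) -> PairSubstitutionSummary:
    """Count transitions/transversions between two aligned sequences.

    ``pairwise_deletion`` drops, per pair, every site where either sequence
    is not an unambiguous base. ``complete_deletion`` restricts first to
    *global_columns* (the alignment-wide gap-free column set) and then
    applies the same per-pair base filter.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    ca = np.array([_CODE.get(s, 255) for s in a.residues], dtype=np.uint8)
    cb = np.array([_CODE.get(s, 255) for s in b.residues], dtype=np.uint8)
    if site_policy == "complete_deletion":
        if global_columns is None:
            raise ValueError("complete_deletion requires global_columns")
        mask = np.zeros(len(ca), dtype=bool)
        mask[global_columns] = True
    elif site_policy == "pairwise_deletion":
        mask = np.ones(len(ca), dtype=bool)
    else:
        raise ValueError(f"unknown site_policy {site_policy!r}")
    ok = mask & (ca != 255) & (cb != 255)
    if not ok.any():
        raise ValueError("no comparable sites between the two sequences")
    xa, xb = ca[ok], cb[ok]
    diff = xa != xb
    same_class = (xa >> 1) == (xb >> 1)  # both purines or both pyrimidines
    s = int((diff & same_class).sum())
    v = int((diff & ~same_class).sum())
    return PairSubstitutionSummary(s, v, int(ok.sum()))


def k2p_distance(P: float, Q: float) -> float:
    """Closed-form Kimura-2-parameter distance from proportions P, Q."""
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValueError("require P, Q >= 0 and P + Q <= 1")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise UndefinedDistanceError(
            f"K2P undefined for P={P:.4f}, Q={Q:.4f} (saturation)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _all_pair_counts(
    codes: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized transition/transversion/site counts for every pair."""
    n = codes.shape[0]
    valid = (codes != 255) & mask[None, :]
    cls = codes >> 1  # 0 = purine, 1 = pyrimidine (meaningless where invalid)
    s = np.zeros((n, n), dtype=np.int64)
    v = np.zeros((n, n), dtype=np.int64)
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        ok = valid[i] & valid[i + 1 :]
        diff = (codes[i] != codes[i + 1 :]) & ok
        same_class = cls[i] == cls[i + 1 :]
        si = (diff & same_class).sum(axis=1)
        vi = (diff & ~same_class).sum(axis=1)
        ni = ok.sum(axis=1)
        s[i, i + 1 :] = s[i + 1 :, i] = si
        v[i, i + 1 :] = v[i + 1 :, i] = vi
        sites[i, i + 1 :] = sites[i + 1 :, i] = ni
    return s, v, sites


def _site_mask(aln: Alignment, site_policy: str) -> np.ndarray:
    if site_policy == "complete_deletion":
        mask = np.zeros(aln.column_count, dtype=bool)
        mask[usable_columns(aln)] = True
        return mask
    if site_policy == "pairwise_deletion":
        return np.ones(aln.column_count, dtype=bool)
    raise ValueError(f"unknown site_policy {site_policy!r}")


def k2p_matrix_from_counts(
    labels: tuple[str, ...],
    s: np.ndarray,
    v: np.ndarray,
    sites: np.ndarray,
) -> DistanceMatrix:
    """Assemble a K2P :class:`DistanceMatrix` from pairwise count arrays."""
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(sites > 0, s / np.maximum(sites, 1), np.nan)
        Q = np.where(sites > 0, v / np.maximum(sites, 1), np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where(
            (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.maximum(w1, 1e-300))
            - 0.25 * np.log(np.maximum(w2, 1e-300)),
            np.nan,
        )
    np.fill_diagonal(d, 0.0)
    iu, ju = np.triu_indices_from(d, k=1)
    undefined = frozenset(
        (labels[i], labels[j]) for i, j in zip(iu, ju) if np.isnan(d[i, j])
    )
    return DistanceMatrix(tuple(labels), d, undefined)


def k2p_distance_matrix(
    aln: Alignment, site_policy: str = "complete_deletion"
) -> DistanceMatrix:
    """All-pairs K2P distances; saturated/incomparable pairs become NaN."""
    codes = _encode(aln)
    mask = _site_mask(aln, site_policy)
    s, v, sites = _all_pair_counts(codes, mask)
    return k2p_matrix_from_counts(aln.ids, s, v, sites)


def saturation_profile(
    aln: Alignment,
    bins: int = 20,
    site_policy: str = "pairwise_deletion",
) -> SaturationProfile:
    """Transitions and transversions of every pair against K2P distance.

    Pairs with undefined distance are omitted from the profile (they are
    beyond the range the K2P correction can express). The crossover
    distance is the smallest bin centre where the binned mean transversion
    count reaches or exceeds the mean transition count — beyond roughly
    that divergence, multiple hits dominate and tree signal decays.
    """
    if len(aln) < 2:
        raise ValueError("need at least two sequences")
    codes = _encode(aln)
    mask = _site_mask(aln, site_policy)
    s_mat, v_mat, sites_mat = _all_pair_counts(codes, mask)
    records = []
    for i, j in itertools.combinations(range(len(aln)), 2):
        s, v, sites = int(s_mat[i, j]), int(v_mat[i, j]), int(sites_mat[i, j])
        if sites == 0:
            continue
        try:
            dist = k2p_distance(s / sites, v / sites)
        except UndefinedDistanceError:
            continue
        records.append((dist, s, v, s / sites, v / sites))
    if not records:
        raise ValueError("no pair has a defined K2P distance")
    rec = np.array(records)
    d = rec[:, 0]
    lo, hi = float(d.min()), float(d.max())
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(d, edges) - 1, 0, bins - 1)
    mean_s = np.full(bins, np.nan)
    mean_v = np.full(bins, np.nan)
    sd_s = np.full(bins, np.nan)
    sd_v = np.full(bins, np.nan)
    for b in range(bins):
        sel = idx == b
        if sel.any():
            mean_s[b] = rec[sel, 1].mean()
            mean_v[b] = rec[sel, 2].mean()
            sd_s[b] = rec[sel, 1].std()
            sd_v[b] = rec[sel, 2].std()
    crossover = None
    for b in range(bins):
        if not (np.isnan(mean_s[b]) or np.isnan(mean_v[b])):
            if mean_v[b] >= mean_s[b] and mean_s[b] + mean_v[b] > 0:
                crossover = float(centers[b])
                break
    return SaturationProfile(
        pair_records=rec,
        bin_centers=centers,
        mean_s=mean_s,
        mean_v=mean_v,
        sd_s=sd_s,
        sd_v=sd_v,
        crossover_distance=crossover,
    )
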