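"""Percentage-sequence-identity OTU clustering, diversity, and rarefaction.

Sequences are binned into Operational Taxonomic Units (OTUs) by percent
identity computed over gap-free alignment columns, in the greedy
seed-joining style of dereplication tools: each sequence, in input order,
joins the first existing OTU whose seed it matches at or above the cutoff,
otherwise it founds a new OTU. A single-linkage variant is also provided.

OTUs are classified as singletons (one member), quasi-singletons (two or
more members, all identical over the compared columns — they behave like
singletons in any distance-based analysis), or multitons. Downstream
statistics are the usual molecular-ecology set: Chao1 richness, the
Shannon-Wiener index in nats, evenness E = H'/ln S, and analytic or
Monte-Carlo rarefaction curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from alnscope.alignment import GAP, Alignment, SequenceRecord

OTU_CLASSES = ("singleton", "quasi_singleton", "multiton")


@dataclass(frozen=True)
class OTU:
    """One cluster: its id, founding seed, and ordered member ids."""

    otu_id: str
    seed_id: str
    member_ids: tuple[str, ...]
    otu_class: str | None = None

    def __post_init__(self) -> None:
        if self.seed_id not in self.member_ids:
            raise ValueError(f"seed {self.seed_id!r} not among members")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class OTUTable:
    """All OTUs from one clustering run at one identity cutoff."""

    otus: tuple[OTU, ...]
    cutoff: float
    treatment: str
    linkage: str
    masking: str

    @property
    def abundance_vector(self) -> np.ndarray:
        return np.array([o.size for o in self.otus], dtype=int)

    @property
    def n_sequences(self) -> int:
        return int(self.abundance_vector.sum())

    def __len__(self) -> int:
        return len(self.otus)


@dataclass(frozen=True)
class DiversitySummary:
    S_obs: int
    chao1: float
    shannon_H: float
    evenness_E: float
    F1: int
    F2: int


@dataclass(frozen=True)
class RarefactionCurve:
    sample_sizes: np.ndarray
    expected_otus: np.ndarray
    method: str
    replicates: int | None = None
    seed: int | None = None
    sd: np.ndarray | None = None  # across-replicate SD (montecarlo only)


def usable_columns(aln: Alignment) -> np.ndarray:
    """0-based indices of columns containing no ``-`` in any sequence.

    This is the global gap-column mask: the identity denominator shared by
    every pair, mirroring tools that drop gap-containing columns up front.
    """
    arr = aln.to_array()
    return np.flatnonzero(~(arr == GAP).any(axis=0))


def pairwise_psi(
    a: SequenceRecord,
    b: SequenceRecord,
    usable: np.ndarray | None = None,
) -> float:
    """Fraction of identical symbols over the usable columns (symmetric)."""
    if len(a) != len(b):
        raise ValueError("records are not from the same alignment")
    arr_a = np.frombuffer(a.residues.encode(), dtype="S1")
    arr_b = np.frombuffer(b.residues.encode(), dtype="S1")
    if usable is not None:
        if len(usable) == 0:
            raise ValueError("no usable columns: identity undefined")
        arr_a = arr_a[usable]
        arr_b = arr_b[usable]
    return float((arr_a == arr_b).mean())


def _identity_matrix(aln: Alignment, masking: str) -> np.ndarray:
    """Symmetric PSI matrix under global or pairwise gap masking."""
    arr = aln.to_array()
    n = len(aln)
    if masking == "global":
        cols = usable_columns(aln)
        if len(cols) == 0:
            raise ValueError("every column contains a gap: identity undefined")
        sub = arr[:, cols]
        eq = sub[:, None, :] == sub[None, :, :]
        return eq.mean(axis=2)
    if masking == "pairwise":
        is_gap = arr == GAP
        psi = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~(is_gap[i] | is_gap[j])
                if not ok.any():
                    raise ValueError(
                        f"no comparable columns between {aln.ids[i]!r} "
                        f"and {aln.ids[j]!r}"
                    )
                psi[i, j] = psi[j, i] = (arr[i, ok] == arr[j, ok]).mean()
        return psi
    raise ValueError(f"unknown masking mode {masking!r}")


def cluster_otus(
    aln: Alignment,
    cutoff: float,
    linkage: str = "seed",
    masking: str = "global",
) -> OTUTable:
    """Bin sequences into OTUs at an identity *cutoff* in (0, 1).

    ``seed`` linkage (default) processes sequences in input order and joins
    each to the first OTU whose seed matches at PSI >= cutoff. ``single``
    linkage takes connected components of the PSI >= cutoff graph. A
    cutoff of 1.0 is rejected: at 100% identity every OTU degenerates to a
    (quasi-)singleton and the downstream distance-area parameters are
    undefined.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be strictly between 0 and 1")
    psi = _identity_matrix(aln, masking)
    n = len(aln)
    ids = aln.ids
    if linkage == "seed":
        seeds: list[int] = []
        members: list[list[int]] = []
        for i in range(n):
            for k, s in enumerate(seeds):
                if psi[i, s] >= cutoff:
                    members[k].append(i)
                    break
            else:
                seeds.append(i)
                members.append([i])
        otus = tuple(
            OTU(
                otu_id=f"OTU{k + 1:03d}",
                seed_id=ids[s],
                member_ids=tuple(ids[m] for m in mem),
            )
            for k, (s, mem) in enumerate(zip(seeds, members))
        )
    elif linkage == "single":
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components

        adj = sp.csr_matrix(psi >= cutoff)
        n_comp, labels = connected_components(adj, directed=False)
        otus_list = []
        seen: dict[int, int] = {}
        for comp in range(n_comp):
            mem = [i for i in range(n) if labels[i] == comp]
            otus_list.append((mem[0], mem))
        # order OTUs by first-member input order for determinism
        otus_list.sort(key=lambda t: t[0])
        otus = tuple(
            OTU(
                otu_id=f"OTU{k + 1:03d}",
                seed_id=ids[mem[0]],
                member_ids=tuple(ids[m] for m in mem),
            )
            for k, (_, mem) in enumerate(otus_list)
        )
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    return OTUTable(
        otus=otus,
        cutoff=cutoff,
        treatment=aln.treatment,
        linkage=linkage,
        masking=masking,
    )


def classify_otus(table: OTUTable, aln: Alignment) -> OTUTable:
    """Label every OTU singleton / quasi_singleton / multiton.

    Quasi-singletons are OTUs of two or more sequences that are identical
    over the usable (gap-free) columns; they carry no internal distance.
    """
    id_to_row = {sid: i for i, sid in enumerate(aln.ids)}
    arr = aln.to_array()
    cols = usable_columns(aln)
    labelled = []
    for otu in table.otus:
        missing = [m for m in otu.member_ids if m not in id_to_row]
        if missing:
            raise KeyError(f"members not in alignment: {', '.join(missing)}")
        if otu.size == 1:
            cls = "singleton"
        else:
            rows = [id_to_row[m] for m in otu.member_ids]
            sub = arr[np.ix_(rows, cols)]
            identical = bool((sub == sub[0]).all())
            cls = "quasi_singleton" if identical else "multiton"
        labelled.append(
            OTU(otu.otu_id, otu.seed_id, otu.member_ids, otu_class=cls)
        )
    return OTUTable(
        otus=tuple(labelled),
        cutoff=table.cutoff,
        treatment=table.treatment,
        linkage=table.linkage,
        masking=table.masking,
    )


def diversity_indices(abundances: np.ndarray | list[int]) -> DiversitySummary:
    """Chao1, Shannon-Wiener H' (nats), and evenness from OTU sizes.

    chao1 = S + F1^2 / (2 F2) with the classic fallback
    S + F1 (F1 - 1) / 2 when no doubletons are present; H' uses natural
    logarithms; E = H' / ln S (0 for a single OTU).
    """
    counts = np.asarray(abundances, dtype=float)
    if counts.size == 0:
        raise ValueError("empty abundance vector")
    if (counts < 1).any():
        raise ValueError("abundances must all be >= 1")
    S = int(counts.size)
    F1 = int((counts == 1).sum())
    F2 = int((counts == 2).sum())
    if F2 > 0:
        chao1 = S + F1 * F1 / (2.0 * F2)
    else:
        chao1 = S + F1 * (F1 - 1) / 2.0
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    evenness = shannon / math.log(S) if S > 1 else 0.0
    return DiversitySummary(
        S_obs=S, chao1=float(chao1), shannon_H=shannon,
        evenness_E=evenness, F1=F1, F2=F2,
    )


def _analytic_rarefaction(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Hypergeometric expectation E[S_n] = sum_i 1 - C(N-n_i, n)/C(N, n)."""
    N = int(counts.sum())

    def log_choose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    expected = np.empty(len(sizes))
    for k, n in enumerate(sizes):
        keep = (N - counts) >= n
        absent = np.zeros(len(counts))
        if keep.any():
            absent[keep] = np.exp(
                log_choose(N - counts[keep], n) - log_choose(N, n)
            )
        expected[k] = float((1.0 - absent).sum())
    return expected


def rarefaction_curve(
    abundances: np.ndarray | list[int],
    method: str = "analytic",
    replicates: int = 100,
    seed: int | None = None,
    stride: int = 1,
) -> RarefactionCurve:
    """Expected OTU count versus subsample size from 1 to N.

    ``analytic`` evaluates the exact hypergeometric expectation;
    ``montecarlo`` averages observed OTU counts over seeded subsamples
    drawn without replacement. The final point always equals S_obs in the
    analytic mode.
    """
    counts = np.asarray(abundances, dtype=int)
    if counts.size == 0 or counts.sum() < 1:
        raise ValueError("empty abundance vector")
    N = int(counts.sum())
    sizes = np.arange(1, N + 1, stride)
    if sizes[-1] != N:
        sizes = np.append(sizes, N)
    if method == "analytic":
        expected = _analytic_rarefaction(counts, sizes)
        return RarefactionCurve(sizes, expected, "analytic")
    if method == "montecarlo":
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(counts.size), counts)
        values = np.zeros((replicates, len(sizes)))
        for r in range(replicates):
            perm = rng.permutation(pool)
            for k, n in enumerate(sizes):
                values[r, k] = len(np.unique(perm[:n]))
        sd = values.std(axis=0, ddof=1) if replicates > 1 else np.zeros(len(sizes))
        return RarefactionCurve(
            sizes, values.mean(axis=0), "montecarlo", replicates, seed, sd
        )
    raise ValueError(f"unknown method {method!r}")
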