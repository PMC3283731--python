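"""Seeded synthetic alignments with planted OTU structure, plus a
sampling-noise profiler.

The generator emulates the architecture of environmental rDNA amplicon
alignments: a handful of divergent clusters (the planted OTUs) over a
column layout of conserved blocks (no substitutions), variable blocks
(where all substitutions land), and gap-rich blocks (per-cell independent
gaps, emulating length-hypervariable spacer regions), with optional
leading/trailing overhangs and sprinkled IUPAC ambiguity codes.

Substitutions follow a K2P-style scheme with a configurable
transition:transversion ratio. Divergences are planted with *exact*
substitution counts (sites drawn without replacement), so the realized
pairwise divergence within a cluster never exceeds the nominal within
divergence — which is what makes identity-cutoff recovery of the planted
partition provable rather than merely probable. ``within_divergence``
(epsilon) is the nominal pairwise divergence between two members of the
same cluster, measured over mutable columns: each member receives
epsilon/2 worth of substitutions relative to its cluster ancestor.
``between_divergence`` (delta) is the nominal pairwise divergence between
cluster ancestors: each ancestor is mutated delta/2 away from a common
root sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from alnscope.alignment import Alignment, SequenceRecord

BLOCK_CLASSES = ("conserved", "variable", "gap_rich")

_BASES = np.array(["A", "C", "G", "T"])
# transition partner for each base index (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])
# transversion partners by base index (A=0, C=1, G=2, T=3):
# purines pair with the two pyrimidines and vice versa
_TRANSVERSIONS = {0: (1, 3), 2: (1, 3), 1: (0, 2), 3: (0, 2)}
_AMBIG = np.array(["R", "Y", "S", "W", "K", "M"])


@dataclass(frozen=True)
class Block:
    """One column block: length, class, and gap probability (gap_rich only)."""

    length: int
    block_class: str
    gap_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("block length must be >= 1")
        if self.block_class not in BLOCK_CLASSES:
            raise ValueError(f"unknown block class {self.block_class!r}")
        if not 0.0 <= self.gap_probability <= 1.0:
            raise ValueError("gap_probability must be in [0, 1]")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic alignment.

    Defaults emulate the scale of a cloned-amplicon survey: 120 sequences
    (40 clones from each of three samples) in ~1 kb alignments with a few
    gap-rich hypervariable blocks, moderate cluster structure, 1% within-
    and 20% between-cluster divergence.
    """

    n_sequences: int = 120
    n_clusters: int = 10
    within_divergence: float = 0.01  # epsilon: pairwise, over mutable columns
    between_divergence: float = 0.20  # delta: pairwise between ancestors
    blocks: tuple[Block, ...] = (
        Block(150, "conserved"),
        Block(300, "variable"),
        Block(100, "gap_rich", gap_probability=0.7),
        Block(250, "variable"),
        Block(80, "gap_rich", gap_probability=0.6),
        Block(120, "conserved"),
    )
    max_overhang: int = 25
    ambiguity_rate: float = 0.001
    ts_tv_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_divergence >= self.between_divergence:
            raise ValueError(
                "within_divergence must be smaller than between_divergence"
            )
        if self.n_clusters > self.n_sequences:
            raise ValueError("more clusters than sequences")

    @property
    def column_count(self) -> int:
        return sum(b.length for b in self.blocks)


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth for a generated fixture."""

    cluster_labels: dict[str, int]  # sequence id -> planted cluster index
    column_classes: tuple[str, ...]  # per column block class
    ancestors: tuple[str, ...]  # ancestral sequence per cluster


def _mutate(
    seq: np.ndarray,
    n_subs: int,
    mutable: np.ndarray,
    rng: np.random.Generator,
    ts_tv_ratio: float,
) -> np.ndarray:
    """Substitute exactly *n_subs* distinct mutable sites of *seq*."""
    out = seq.copy()
    if n_subs == 0:
        return out
    sites = rng.choice(mutable, size=min(n_subs, len(mutable)), replace=False)
    p_transition = ts_tv_ratio / (ts_tv_ratio + 1.0)
    for site in sites:
        base = out[site]
        if rng.random() < p_transition:
            out[site] = _TRANSITION[base]
        else:
            a, b = _TRANSVERSIONS[int(base)]
            out[site] = a if rng.random() < 0.5 else b
    return out


def generate_alignment(spec: FixtureSpec) -> tuple[Alignment, FixtureTruth]:
    """Generate a seeded alignment with planted clusters; returns truth too."""
    rng = np.random.default_rng(spec.seed)
    L = spec.column_count
    column_classes: list[str] = []
    for block in spec.blocks:
        column_classes.extend([block.block_class] * block.length)
    classes = np.array(column_classes)
    mutable = np.flatnonzero(classes != "conserved")
    if len(mutable) == 0:
        raise ValueError("no mutable (non-conserved) columns in spec")

    root = rng.integers(0, 4, size=L)
    n_between = round(spec.between_divergence / 2.0 * len(mutable))
    n_within = round(spec.within_divergence / 2.0 * len(mutable))
    ancestors = [
        _mutate(root, n_between, mutable, rng, spec.ts_tv_ratio)
        for _ in range(spec.n_clusters)
    ]

    # round-robin cluster sizes: as even as possible, deterministic
    assignment = [i % spec.n_clusters for i in range(spec.n_sequences)]

    gap_prob = np.zeros(L)
    for start, block in zip(
        np.cumsum([0] + [b.length for b in spec.blocks[:-1]]), spec.blocks
    ):
        if block.block_class == "gap_rich":
            gap_prob[start : start + block.length] = block.gap_probability

    records = []
    labels: dict[str, int] = {}
    for idx, cluster in enumerate(assignment):
        member = _mutate(
            ancestors[cluster], n_within, mutable, rng, spec.ts_tv_ratio
        )
        chars = _BASES[member].copy()
        gaps = rng.random(L) < gap_prob
        chars[gaps] = "-"
        if spec.ambiguity_rate > 0:
            amb = (rng.random(L) < spec.ambiguity_rate) & ~gaps
            chars[amb] = rng.choice(_AMBIG, size=int(amb.sum()))
        lead = int(rng.integers(0, spec.max_overhang + 1)) if spec.max_overhang else 0
        trail = int(rng.integers(0, spec.max_overhang + 1)) if spec.max_overhang else 0
        if lead:
            chars[:lead] = "-"
        if trail:
            chars[-trail:] = "-"
        seq_id = f"seq{idx + 1:03d}_c{cluster + 1}"
        labels[seq_id] = cluster
        records.append(SequenceRecord(seq_id, "".join(chars)))

    truth = FixtureTruth(
        cluster_labels=labels,
        column_classes=tuple(column_classes),
        ancestors=tuple("".join(_BASES[a]) for a in ancestors),
    )
    return Alignment(tuple(records), treatment="T1"), truth


def divergence_ladder(
    n_steps: int = 30,
    step_rate: float = 0.05,
    length: int = 800,
    ts_tv_ratio: float = 2.0,
    seed: int | None = None,
) -> Alignment:
    """Chain of sequences at steadily increasing divergence.

    Starting from a random root, each sequence applies ``step_rate *
    length`` substitution events (sites drawn *with* replacement, so
    multiple hits accumulate) to its predecessor. Pairs of chain members
    then span raw divergences from ~step_rate up to saturation, which is
    exactly the input a substitution-saturation profile needs: transitions
    outnumber transversions at short distances (for ts:tv > 1) and are
    overtaken once multiple hits randomize the fast transition sites.
    """
    if n_steps < 2:
        raise ValueError("need at least two steps")
    rng = np.random.default_rng(seed)
    p_transition = ts_tv_ratio / (ts_tv_ratio + 1.0)
    n_events = max(1, round(step_rate * length))
    seq = rng.integers(0, 4, size=length)
    records = [SequenceRecord("step000", "".join(_BASES[seq]))]
    for k in range(1, n_steps):
        seq = seq.copy()
        sites = rng.integers(0, length, size=n_events)
        for site in sites:
            base = seq[site]
            if rng.random() < p_transition:
                seq[site] = _TRANSITION[base]
            else:
                a, b = _TRANSVERSIONS[int(base)]
                seq[site] = a if rng.random() < 0.5 else b
        records.append(SequenceRecord(f"step{k:03d}", "".join(_BASES[seq])))
    return Alignment(tuple(records), treatment="T1")


def resampling_profile(
    pool_proportions: list[float] | np.ndarray,
    pool_size: int,
    sample_size: int,
    replicates: int = 100,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Sampling noise when drawing *sample_size* items from a finite pool.

    The pool holds *pool_size* items split into classes by
    *pool_proportions* (must sum to 1). Per replicate, *sample_size* items
    are drawn without replacement; returned are the per-class mean
    percentage and its standard deviation across replicates, quantifying
    how faithfully a small clone library reflects the composition of the
    underlying community.
    """
    props = np.asarray(pool_proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("pool proportions must sum to 1")
    if sample_size > pool_size:
        raise ValueError("sample_size exceeds pool_size")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    counts = np.round(props * pool_size).astype(int)
    counts[-1] = pool_size - counts[:-1].sum()  # absorb rounding in last class
    rng = np.random.default_rng(seed)
    k = len(props)
    percents = np.empty((replicates, k))
    for r in range(replicates):
        drawn = rng.multivariate_hypergeometric(counts, sample_size)
        percents[r] = 100.0 * drawn / sample_size
    return {
        "class_counts": counts,
        "mean_percent": percents.mean(axis=0),
        "sd_percent": percents.std(axis=0, ddof=1) if replicates > 1 else np.zeros(k),
    }
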