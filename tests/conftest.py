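import numpy as np
import pytest

from alnscope import Alignment, Block, FixtureSpec, SequenceRecord, generate_alignment


def make_alignment(rows: dict[str, str], treatment: str = "T1") -> Alignment:
    return Alignment(
        tuple(SequenceRecord(k, v) for k, v in rows.items()), treatment=treatment
    )


@pytest.fixture
def tiny_aln() -> Alignment:
    return make_alignment(
        {
            "s1": "ACGTACGT",
            "s2": "ACGTACGA",
            "s3": "AC-TACGT",
        }
    )


@pytest.fixture
def conserved_aln() -> Alignment:
    return make_alignment({f"s{i}": "ACGTACGT" for i in range(1, 5)})


def clean_cluster_spec(seed: int, **overrides) -> FixtureSpec:
    """Gap-free all-variable fixture where identity-cutoff recovery of the
    planted clusters is guaranteed by construction."""
    params = dict(
        n_sequences=30,
        n_clusters=3,
        within_divergence=0.01,
        between_divergence=0.20,
        blocks=(Block(600, "variable"),),
        max_overhang=0,
        ambiguity_rate=0.0,
        seed=seed,
    )
    params.update(overrides)
    return FixtureSpec(**params)


def true_partition(truth) -> set[frozenset[str]]:
    clusters: dict[int, set[str]] = {}
    for sid, cl in truth.cluster_labels.items():
        clusters.setdefault(cl, set()).add(sid)
    return {frozenset(s) for s in clusters.values()}


@pytest.fixture
def planted() -> tuple:
    spec = clean_cluster_spec(seed=11)
    return generate_alignment(spec)


def random_alignment(rng: np.random.Generator, n: int, L: int, with_gaps=True):
    symbols = list("ACGT") + (["-", "N", "R", "Y"] if with_gaps else [])
    mat = rng.choice(symbols, size=(n, L))
    return Alignment(
        tuple(SequenceRecord(f"r{i}", "".join(row)) for i, row in enumerate(mat))
    )
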