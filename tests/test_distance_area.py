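import numpy as np
import pytest

from alnscope import (
    build_nj_tree,
    classify_otus,
    cluster_otus,
    cutoff_sweep,
    distance_area_table,
    generate_alignment,
    k2p_distance_matrix,
    plot_coordinates,
)
from alnscope.otu import OTU, OTUTable

from conftest import clean_cluster_spec


def _table(otus):
    return OTUTable(otus=tuple(otus), cutoff=0.95, treatment="T1",
                    linkage="seed", masking="global")


def _areas_from_dints(dints: dict[str, tuple[int, float]], N: int, mode="sum_internal"):
    """Build a distance-area table from explicit (n, d_int) pairs."""
    otus = []
    for oid, (n, _) in dints.items():
        members = tuple(f"{oid}_m{i}" for i in range(n))
        cls = "singleton" if n == 1 else "multiton"
        otus.append(OTU(oid, members[0], members, otu_class=cls))
    internal = {oid: d for oid, (n, d) in dints.items() if n > 1}
    return distance_area_table(
        _table(otus), tree=None, N=N, roda_mode=mode, internal_distances=internal
    )


class TestFormulas:
    def test_ioda_formula_as_stated(self):
        areas = _areas_from_dints({"O1": (53, 0.04)}, N=120)
        assert areas[0].ioda == pytest.approx(100 * 0.04 * 53 / 120)
        # single included OTU: RODA self-normalizes to 100 n / N
        assert areas[0].roda == pytest.approx(100 * 53 / 120)

    def test_roda_sum_normalization(self):
        areas = _areas_from_dints({"O1": (10, 0.02), "O2": (5, 0.04)}, N=60)
        total_d = 0.06
        assert areas[0].roda == pytest.approx(100 * 0.02 * 10 / (60 * total_d))
        assert areas[1].roda == pytest.approx(100 * 0.04 * 5 / (60 * total_d))

    def test_roda_max_normalization_mode(self):
        areas = _areas_from_dints(
            {"O1": (10, 0.02), "O2": (5, 0.04)}, N=60, mode="max_internal"
        )
        assert areas[0].roda == pytest.approx(100 * 0.02 * 10 / (60 * 0.04))

    def test_ioda_linear_in_n_and_d(self):
        base = _areas_from_dints({"O1": (4, 0.02)}, N=100)[0].ioda
        assert _areas_from_dints({"O1": (8, 0.02)}, N=100)[0].ioda == pytest.approx(
            2 * base
        )
        assert _areas_from_dints({"O1": (4, 0.04)}, N=100)[0].ioda == pytest.approx(
            2 * base
        )

    def test_singletons_and_quasi_singletons_excluded(self):
        otus = (
            OTU("S", "S_m0", ("S_m0",), otu_class="singleton"),
            OTU("Q", "Q_m0", ("Q_m0", "Q_m1"), otu_class="quasi_singleton"),
            OTU("M", "M_m0", ("M_m0", "M_m1"), otu_class="multiton"),
        )
        areas = distance_area_table(
            _table(otus), tree=None, N=10,
            internal_distances={"Q": 0.0, "M": 0.03},
        )
        by_id = {a.otu_id: a for a in areas}
        assert by_id["S"].excluded and by_id["S"].ioda is None
        assert by_id["Q"].excluded and by_id["Q"].roda is None
        assert not by_id["M"].excluded

    def test_roda_sum_bounded_by_100(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(1, 8))
            dints = {
                f"O{i}": (int(rng.integers(2, 10)), float(rng.uniform(0.01, 0.1)))
                for i in range(k)
            }
            N = sum(n for n, _ in dints.values()) + int(rng.integers(0, 5))
            total = sum(a.roda for a in _areas_from_dints(dints, N))
            assert total <= 100 + 1e-9


class TestPlot:
    def test_n2_otus_sit_exactly_on_min_line(self):
        areas = _areas_from_dints(
            {"A": (2, 0.01), "B": (5, 0.03), "C": (2, 0.05)}, N=20
        )
        plot = plot_coordinates(areas, N=20)
        scale = {p[0]: p for p in plot.points}
        total = 0.01 + 0.03 + 0.05
        for oid, n, d in (("A", 2, 0.01), ("C", 2, 0.05)):
            _, x, y = scale[oid]
            assert y == pytest.approx(100 * 2 * d / (20 * total))
        by_id = {a.otu_id: a for a in areas}
        assert by_id["A"].on_min_line and by_id["C"].on_min_line
        assert not by_id["B"].on_min_line

    def test_points_between_boundary_lines(self):
        areas = _areas_from_dints(
            {"A": (2, 0.02), "B": (7, 0.04), "C": (20, 0.01)}, N=20
        )
        plot = plot_coordinates(areas, N=20)
        total = 0.02 + 0.04 + 0.01
        for _, x, y in plot.points:
            y_min = 100 * 2 * x / (20 * total)
            y_max = 100 * 20 * x / (20 * total)
            assert y_min - 1e-12 <= y <= y_max + 1e-12

    def test_n_equal_N_otu_on_max_line(self):
        areas = _areas_from_dints({"A": (20, 0.03)}, N=20)
        plot = plot_coordinates(areas, N=20)
        _, x, y = plot.points[0]
        # single OTU: its point must coincide with the max line at x
        slope = plot.max_line_y[-1] / plot.d_grid[-1]
        assert y == pytest.approx(slope * x)

    def test_empty_table_gives_boundary_only_plot(self):
        plot = plot_coordinates([], N=10)
        assert plot.points == ()
        assert len(plot.min_line_y) == len(plot.d_grid)

    def test_serialization_round_trip(self):
        import json

        areas = _areas_from_dints({"A": (3, 0.02)}, N=10)
        plot = plot_coordinates(areas, N=10, cutoff_guides=(0.05,))
        payload = json.loads(json.dumps(plot.to_dict()))
        assert payload["cutoff_guides"] == [0.05]
        assert payload["points"][0]["otu_id"] == "A"


class TestSweep:
    def test_parent_child_links_follow_seed(self):
        # two subclusters at ~2% divergence inside clusters 20% apart:
        # one OTU at 0.95 splits into two at 0.99
        spec = clean_cluster_spec(
            seed=21, n_sequences=24, n_clusters=6,
            within_divergence=0.025, between_divergence=0.30,
        )
        aln, truth = generate_alignment(spec)
        tree = build_nj_tree(k2p_distance_matrix(aln))
        sweep = cutoff_sweep(aln, [0.95, 0.99], tree)
        n_coarse = len(sweep.otu_tables[0.95])
        n_fine = len(sweep.otu_tables[0.99])
        assert n_fine >= n_coarse
        lineage = sweep.lineages[0]
        assert (lineage.parent_cutoff, lineage.child_cutoff) == (0.95, 0.99)
        # every child links to exactly one parent; all parents exist
        parents = {o.otu_id for o in sweep.otu_tables[0.95].otus}
        children = [c for _, c in lineage.links]
        assert sorted(children) == sorted(
            o.otu_id for o in sweep.otu_tables[0.99].otus
        )
        assert all(p in parents for p, _ in lineage.links)

    def test_identical_partitions_give_identity_links(self, planted):
        aln, _ = planted
        tree = build_nj_tree(k2p_distance_matrix(aln))
        sweep = cutoff_sweep(aln, [0.95, 0.97], tree)
        t95 = {frozenset(o.member_ids) for o in sweep.otu_tables[0.95].otus}
        t97 = {frozenset(o.member_ids) for o in sweep.otu_tables[0.97].otus}
        assert t95 == t97  # guaranteed recovery at both cutoffs
        n_parents = len({p for p, _ in sweep.lineages[0].links})
        assert n_parents == len(t95)

    def test_unsorted_cutoffs_rejected(self, planted):
        aln, _ = planted
        with pytest.raises(ValueError, match="increasing"):
            cutoff_sweep(aln, [0.99, 0.95], tree=None)
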