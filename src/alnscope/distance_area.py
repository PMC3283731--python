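"""OTU distance-area parameters (IODA / RODA) and plot coordinates.

The "distance area" of an OTU is the product of its internal distance
d_int (maximum MRCA-to-member path length, K2P scale) and its member
count n. Expressed as a percentage of the maximum possible area — which
equals the total number of sequences N in the alignment — this gives the
Internal OTU Distance Area:

    IODA = 100 * d_int * n / N.

The Realized OTU Distance Area replaces the maximum possible distance by
the distance actually covered by all OTUs together; in the default
``sum_internal`` mode the correction divides by the summed internal
distances of every included OTU:

    RODA = 100 * d_int * n / (N * sum_j d_int_j).

Both parameters are undefined for singletons and quasi-singletons (zero
internal distance: they act like singletons), so those OTUs are listed but
excluded. In a RODA-versus-d_int plot, OTUs of two sequences fall exactly
on the minimum-area boundary line (n = 2) and no OTU can exceed the
maximum line (n = N); movement of points under cutoff changes exposes how
OTUs split as the identity requirement tightens.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from alnscope.alignment import Alignment
from alnscope.otu import OTUTable, classify_otus, cluster_otus
from alnscope.trees import otu_internal_distance

RODA_MODES = ("sum_internal", "max_internal")


@dataclass(frozen=True)
class OTUDistanceArea:
    otu_id: str
    n: int
    d_int: float | None
    ioda: float | None
    roda: float | None
    otu_class: str
    excluded: bool

    @property
    def on_min_line(self) -> bool:
        return (not self.excluded) and self.n == 2


@dataclass(frozen=True)
class DistanceAreaPlot:
    """Serializable coordinates: points plus boundary/guide loci.

    ``min_line`` and ``max_line`` give (slope,) coefficients of the area
    lines y = slope * d for n = 2 and n = N under the same normalization
    as the points, evaluated over ``d_grid``.
    """

    points: tuple[tuple[str, float, float], ...]  # (otu_id, x=d_int, y)
    d_grid: np.ndarray
    min_line_y: np.ndarray
    max_line_y: np.ndarray
    cutoff_guides: tuple[float, ...]
    y_axis: str

    def to_dict(self) -> dict:
        return {
            "y_axis": self.y_axis,
            "points": [
                {"otu_id": oid, "d_int": x, "y": y} for oid, x, y in self.points
            ],
            "d_grid": self.d_grid.tolist(),
            "min_line_y": self.min_line_y.tolist(),
            "max_line_y": self.max_line_y.tolist(),
            "cutoff_guides": list(self.cutoff_guides),
        }


def distance_area_table(
    otus: OTUTable,
    tree: dendropy.Tree,
    N: int,
    roda_mode: str = "sum_internal",
    root_policy: str = "midpoint",
    internal_distances: dict[str, float] | None = None,
) -> list[OTUDistanceArea]:
    """IODA and RODA for every OTU in *otus*; see the module docstring.

    OTUs must already carry classes (see :func:`alnscope.otu.classify_otus`).
    Singletons and quasi-singletons (d_int = 0) are returned with
    ``excluded=True`` and no area values. *internal_distances* can supply
    precomputed d_int values keyed by otu_id (e.g. from the pairwise
    fallback); otherwise the tree-MRCA definition is used.
    """
    if roda_mode not in RODA_MODES:
        raise ValueError(f"unknown roda_mode {roda_mode!r}")
    if N < 2:
        raise ValueError("need at least two sequences")
    rows: list[tuple] = []
    for otu in otus.otus:
        cls = otu.otu_class
        if cls is None:
            raise ValueError("OTU table lacks classes; run classify_otus first")
        if cls == "singleton":
            rows.append((otu, None))
            continue
        if internal_distances is not None:
            d_int = internal_distances[otu.otu_id]
        else:
            d_int = otu_internal_distance(tree, otu, root_policy)
        rows.append((otu, d_int))

    included = [
        (otu, d) for otu, d in rows if d is not None and d > 0
    ]
    total_d = sum(d for _, d in included)
    max_d = max((d for _, d in included), default=0.0)
    denom = total_d if roda_mode == "sum_internal" else max_d

    out: list[OTUDistanceArea] = []
    for otu, d_int in rows:
        if d_int is None or d_int <= 0:
            out.append(
                OTUDistanceArea(
                    otu_id=otu.otu_id,
                    n=otu.size,
                    d_int=d_int,
                    ioda=None,
                    roda=None,
                    otu_class=otu.otu_class,
                    excluded=True,
                )
            )
            continue
        ioda = 100.0 * d_int * otu.size / N
        roda = ioda / denom if denom > 0 else None
        out.append(
            OTUDistanceArea(
                otu_id=otu.otu_id,
                n=otu.size,
                d_int=d_int,
                ioda=ioda,
                roda=roda,
                otu_class=otu.otu_class,
                excluded=False,
            )
        )
    return out


def plot_coordinates(
    table: list[OTUDistanceArea],
    N: int,
    cutoff_guides: tuple[float, ...] = (),
    y_axis: str = "roda",
    grid_points: int = 50,
) -> DistanceAreaPlot:
    """Distance-area plot coordinates for the included OTUs.

    x is the internal distance, y is RODA (default) or IODA; the boundary
    loci are the same quantity evaluated at n = 2 (minimum) and n = N
    (maximum) as functions of d, so every point lies between them.
    """
    if y_axis not in ("roda", "ioda"):
        raise ValueError("y_axis must be 'roda' or 'ioda'")
    included = [t for t in table if not t.excluded]
    points = tuple(
        (t.otu_id, float(t.d_int), float(getattr(t, y_axis)))
        for t in included
        if getattr(t, y_axis) is not None
    )
    d_max = max((t.d_int for t in included), default=0.05)
    d_grid = np.linspace(0.0, d_max * 1.1, grid_points)
    if y_axis == "ioda":
        scale = 100.0 / N
    else:
        # recover the shared normalization from any included point
        total = sum(t.d_int for t in included)
        scale = 100.0 / (N * total) if total > 0 else 0.0
    min_line = 2.0 * scale * d_grid
    max_line = N * scale * d_grid
    return DistanceAreaPlot(
        points=points,
        d_grid=d_grid,
        min_line_y=min_line,
        max_line_y=max_line,
        cutoff_guides=tuple(cutoff_guides),
        y_axis=y_axis,
    )


@dataclass(frozen=True)
class OTULineage:
    """Parent/child OTU links between two consecutive identity cutoffs."""

    parent_cutoff: float
    child_cutoff: float
    links: tuple[tuple[str, str], ...]  # (parent otu_id, child otu_id)


@dataclass(frozen=True)
class CutoffSweep:
    tables: dict[float, list[OTUDistanceArea]]
    otu_tables: dict[float, OTUTable]
    lineages: tuple[OTULineage, ...]


def cutoff_sweep(
    aln: Alignment,
    cutoffs: list[float],
    tree: dendropy.Tree,
    roda_mode: str = "sum_internal",
    linkage: str = "seed",
    masking: str = "global",
) -> CutoffSweep:
    """Distance-area tables across increasing cutoffs plus OTU lineages.

    Each child OTU at the stricter cutoff is linked to the parent OTU (at
    the previous cutoff) that contains the child's seed sequence, making
    OTU splits traceable as the identity requirement tightens.
    """
    if any(not 0 < c < 1 for c in cutoffs):
        raise ValueError("cutoffs must lie in (0, 1)")
    if list(cutoffs) != sorted(set(cutoffs)):
        raise ValueError("cutoffs must be strictly increasing")
    N = len(aln)
    otu_tables: dict[float, OTUTable] = {}
    tables: dict[float, list[OTUDistanceArea]] = {}
    for c in cutoffs:
        table = classify_otus(cluster_otus(aln, c, linkage, masking), aln)
        otu_tables[c] = table
        tables[c] = distance_area_table(table, tree, N, roda_mode)
    lineages = []
    for parent_c, child_c in zip(cutoffs[:-1], cutoffs[1:]):
        member_to_parent = {
            m: otu.otu_id
            for otu in otu_tables[parent_c].otus
            for m in otu.member_ids
        }
        links = tuple(
            (member_to_parent[child.seed_id], child.otu_id)
            for child in otu_tables[child_c].otus
        )
        lineages.append(OTULineage(parent_c, child_c, links))
    return CutoffSweep(tables=tables, otu_tables=otu_tables, lineages=tuple(lineages))
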