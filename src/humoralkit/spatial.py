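"""Spatial mIHC analyses on centroid tables.

Implements seeded community detection (cells positive for any of CD3,
CD8, CD20 linked within 10 µm), mean-shift centroiding with equal-area
concentric ring density profiles, radial-gradient aggregate enrichment
with union-of-disks areas, and KNN/Leiden plasma-cell infiltration
scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import Point, box
from shapely.ops import unary_union
from shapely.prepared import prep
from sklearn.neighbors import NearestNeighbors

from ._constants import TLS_SEED_MARKERS

logger = logging.getLogger(__name__)

DEFAULT_LINK_DIST_UM = 10.0
DEFAULT_MIN_COMMUNITY_SIZE = 10
DEFAULT_BANDWIDTH_UM = 20.0
N_RINGS = 10
PROFILE_MARKERS = ("CD20", "CD3", "CD8", "MZB1")

# phenotype name -> (required-positive markers, required-negative markers)
DEFAULT_PHENOTYPES: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    "MZB1+": (("MZB1",), ()),
    "CD3+CD8+": (("CD3", "CD8"), ()),
    "CD68+": (("CD68",), ()),
    "CD20+": (("CD20",), ()),
    "CD3+CD8-FOXP3+": (("CD3", "FOXP3"), ("CD8",)),
}


@dataclass
class SpatialCommunity:
    community_id: int
    members: np.ndarray  # indices into the input cell table
    centroid: Optional[Tuple[float, float]] = None
    effective_area_um2: Optional[float] = None
    ring_radii: Optional[np.ndarray] = None
    ring_cumulative_density: Dict[str, np.ndarray] = field(default_factory=dict)
    ring_cumulative_counts: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def _coords(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x_um", "y_um"]].to_numpy(dtype=float)


def _connected_components(points: np.ndarray, link_dist: float) -> np.ndarray:
    """Component label per point under the <= link_dist adjacency."""
    n = len(points)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = cKDTree(points)
    for i, j in tree.query_pairs(link_dist):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def detect_tls_communities(
    cells: pd.DataFrame,
    seed_markers: Sequence[str] = TLS_SEED_MARKERS,
    link_dist_um: float = DEFAULT_LINK_DIST_UM,
    min_community_size: int = DEFAULT_MIN_COMMUNITY_SIZE,
) -> List[SpatialCommunity]:
    """Connected components of seed-marker-positive cells within 10 µm.

    Only cells positive for ANY seed marker participate; components
    smaller than *min_community_size* are discarded. Returned communities
    carry membership only — complete them with :func:`radial_profile`.
    """
    if link_dist_um <= 0:
        raise ValueError("link_dist_um must be > 0")
    positive = cells[list(seed_markers)].astype(bool).any(axis=1).to_numpy()
    idx = np.flatnonzero(positive)
    if idx.size == 0:
        return []
    labels = _connected_components(_coords(cells)[idx], link_dist_um)
    communities = []
    for lab in range(labels.max() + 1):
        members = idx[labels == lab]
        if len(members) >= min_community_size:
            communities.append(SpatialCommunity(len(communities), members))
    return communities


def _mean_shift_mode(points: np.ndarray, bandwidth: float,
                     max_iter: int = 200, tol: float = 1e-6) -> np.ndarray:
    """Flat-kernel mean shift seeded at the coordinate mean."""
    center = points.mean(axis=0)
    for _ in range(max_iter):
        inside = points[np.hypot(*(points - center).T) <= bandwidth]
        if len(inside) == 0:
            break
        new = inside.mean(axis=0)
        if np.hypot(*(new - center)) < tol:
            center = new
            break
        center = new
    return center


def _hull_area(points: np.ndarray) -> Tuple[float, bool]:
    """(area, degenerate_fallback_used). Falls back to a bounding circle."""
    try:
        return float(ConvexHull(points).volume), False
    except (QhullError, ValueError):
        center = points.mean(axis=0)
        r = float(np.hypot(*(points - center).T).max())
        logger.warning("degenerate hull; using bounding-circle area")
        return float(np.pi * max(r, 1e-9) ** 2), True


def radial_profile(
    community: SpatialCommunity,
    cells: pd.DataFrame,
    n_rings: int = N_RINGS,
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM,
    markers: Sequence[str] = PROFILE_MARKERS,
) -> SpatialCommunity:
    """Complete a community with centroid, area and ring density profiles.

    The centroid is the flat-kernel mean-shift mode of the member
    coordinates; ring radii realize equal-area disks on the circle
    equivalent to the convex-hull area (``pi r_k^2 = (k/n) * hull_area``),
    with the outermost ring extended to the farthest member. Cumulative
    marker densities count ALL cells (members or not) within each radius.
    """
    if community.size < 3:
        raise ValueError("radial_profile requires >= 3 member cells")
    all_xy = _coords(cells)
    member_xy = all_xy[community.members]
    centroid = _mean_shift_mode(member_xy, bandwidth_um)
    area, _degenerate = _hull_area(member_xy)
    r_eff = np.sqrt(area / np.pi)
    radii = r_eff * np.sqrt(np.arange(1, n_rings + 1) / n_rings)
    max_member_dist = float(np.hypot(*(member_xy - centroid).T).max())
    radii[-1] = max(radii[-1], max_member_dist)

    dist_all = np.hypot(*(all_xy - centroid).T)
    community.centroid = (float(centroid[0]), float(centroid[1]))
    community.effective_area_um2 = area
    community.ring_radii = radii
    for marker in markers:
        positive = cells[marker].astype(bool).to_numpy()
        counts = np.array([(positive & (dist_all <= r)).sum() for r in radii])
        if np.any(np.diff(counts) < 0):  # cumulative by construction
            raise AssertionError("cumulative ring counts decreased")
        community.ring_cumulative_counts[marker] = counts
        community.ring_cumulative_density[marker] = counts / (np.pi * radii ** 2)
    return community


def profiles_long_table(communities: Sequence[SpatialCommunity]) -> pd.DataFrame:
    """Ring profiles in long format (one row per community/marker/ring)."""
    rows = []
    for com in communities:
        if com.ring_radii is None:
            continue
        for marker, dens in com.ring_cumulative_density.items():
            counts = com.ring_cumulative_counts[marker]
            for k, (r, d, c) in enumerate(zip(com.ring_radii, dens, counts), 1):
                rows.append((com.community_id, com.size, marker, k,
                             float(r), int(c), float(d)))
    return pd.DataFrame(
        rows, columns=["community_id", "n_members", "marker", "ring",
                       "radius_um", "cumulative_count", "cumulative_density"],
    )


# --------------------------------------------------------------------------
# radial-gradient aggregate enrichment
# --------------------------------------------------------------------------

def _phenotype_mask(cells: pd.DataFrame,
                    spec: Tuple[Tuple[str, ...], Tuple[str, ...]]) -> np.ndarray:
    pos, neg = spec
    mask = np.ones(len(cells), dtype=bool)
    for m in pos:
        mask &= cells[m].astype(bool).to_numpy()
    for m in neg:
        mask &= ~cells[m].astype(bool).to_numpy()
    return mask


def aggregate_enrichment(
    cells: pd.DataFrame,
    query_markers: Sequence[str],
    radius_um: float = 10.0,
    phenotypes: Optional[Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]]] = None,
    field_bounds: Optional[Tuple[float, float, float, float]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Grow aggregates from query-marker-positive cells; score enrichment.

    Aggregates are connected components of query-positive cells under the
    *radius_um* linkage; each aggregate's area is the union of
    radius_um-disks around its members. Per phenotype, enrichment is the
    cell density inside aggregates over the density outside (within
    *field_bounds*, defaulting to the bounding box of all cells).

    Returns ``(enrichment table, aggregate table)``.
    """
    if not 1 <= len(query_markers) <= 3:
        raise ValueError("query_markers must contain 1–3 markers")
    phenotypes = phenotypes or DEFAULT_PHENOTYPES
    xy = _coords(cells)
    positive = cells[list(query_markers)].astype(bool).any(axis=1).to_numpy()
    idx = np.flatnonzero(positive)
    if idx.size == 0:
        return (pd.DataFrame(columns=["phenotype", "n_inside", "n_outside",
                                      "density_inside", "density_outside",
                                      "enrichment"]),
                pd.DataFrame(columns=["aggregate_id", "n_members", "area_um2"]))

    labels = _connected_components(xy[idx], radius_um)
    agg_rows = []
    shapes = []
    for lab in range(labels.max() + 1):
        members = idx[labels == lab]
        shape = unary_union(
            [Point(x, y).buffer(radius_um, quad_segs=96) for x, y in xy[members]]
        )
        shapes.append(shape)
        agg_rows.append((lab, len(members), float(shape.area)))
    aggregates = pd.DataFrame(agg_rows,
                              columns=["aggregate_id", "n_members", "area_um2"])

    union_shape = unary_union(shapes)
    if field_bounds is None:
        x0, y0 = xy.min(axis=0)
        x1, y1 = xy.max(axis=0)
        field_bounds = (float(x0), float(y0), float(x1), float(y1))
    field = box(*field_bounds)
    inside_area = float(union_shape.intersection(field).area)
    outside_area = max(float(field.area) - inside_area, 0.0)

    prepared = prep(union_shape)
    inside_mask = np.array([prepared.contains(Point(x, y)) for x, y in xy])

    rows = []
    for name, spec in phenotypes.items():
        mask = _phenotype_mask(cells, spec)
        n_in = int((mask & inside_mask).sum())
        n_out = int((mask & ~inside_mask).sum())
        d_in = n_in / inside_area if inside_area > 0 else np.nan
        d_out = n_out / outside_area if outside_area > 0 else np.nan
        if d_out and np.isfinite(d_out):
            enrich = d_in / d_out
        else:
            enrich = np.inf if (d_in and np.isfinite(d_in)) else np.nan
        rows.append((name, n_in, n_out, d_in, d_out, enrich))
    enrichment = pd.DataFrame(
        rows, columns=["phenotype", "n_inside", "n_outside",
                       "density_inside", "density_outside", "enrichment"],
    )
    return enrichment, aggregates


# --------------------------------------------------------------------------
# KNN / Leiden infiltration scoring
# --------------------------------------------------------------------------

def infiltration_scores(
    cells: pd.DataFrame,
    k: int = 10,
    leiden_resolution: float = 1.0,
    seed: int = 0,
    marker: str = "MZB1",
) -> Tuple[pd.DataFrame, float]:
    """Leiden communities on the union-symmetrized KNN graph; MZB1 ratios.

    Per community, ``infiltration_score = n_marker_positive / n_cells``;
    the patient-level score is the unweighted mean over communities.
    """
    n = len(cells)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    xy = _coords(cells)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(xy)
    _, nbr = nn.kneighbors(xy)
    edges = set()
    for i in range(n):
        for j in nbr[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))  # union symmetrization
    graph = igraph.Graph(n=n, edges=sorted(edges))
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=leiden_resolution,
        seed=seed,
    )
    positive = cells[marker].astype(bool).to_numpy()
    rows = []
    for cid, members in enumerate(partition):
        members = np.asarray(members)
        n_pos = int(positive[members].sum())
        rows.append((cid, len(members), n_pos, n_pos / len(members)))
    table = pd.DataFrame(
        rows, columns=["community_id", "n_cells", "n_mzb1_pos", "infiltration_score"]
    )
    return table, float(table["infiltration_score"].mean())


def compare_infiltration(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p on patient-level mean scores."""
    res = stats.mannwhitneyu(group_a, group_b, alternative="two-sided")
    return float(res.pvalue)
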