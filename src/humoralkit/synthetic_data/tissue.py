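"""Synthetic mIHC centroid fields with separable marker-positive aggregates.

Aggregate members are placed sequentially within 8 µm of an existing
member, which guarantees each aggregate is a single connected component
under the downstream 10-µm linkage rule; aggregate centers are kept far
enough apart that distinct aggregates can never link.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .._constants import SPATIAL_MARKERS
from .specs import SpatialSpec, _spawn_rng

_CHAIN_STEP_UM = 8.0  # < 10 µm linkage distance, keeps aggregates connected


class AggregatePlacementError(RuntimeError):
    """Raised when aggregate centers cannot satisfy the separation gap."""


def _place_centers(spec: SpatialSpec, rng: np.random.Generator) -> np.ndarray:
    margin = spec.aggregate_radius_um
    # member-to-member gap > min_aggregate_gap_um requires center distance
    # greater than gap + 2 * radius
    min_center_dist = spec.min_aggregate_gap_um + 2.0 * spec.aggregate_radius_um
    lo = np.array([margin, margin])
    hi = np.array([spec.field_width_um - margin, spec.field_height_um - margin])
    if np.any(hi <= lo):
        raise AggregatePlacementError("field too small for aggregate radius")
    centers: list = []
    max_tries = 500 * max(spec.n_aggregates, 1)
    tries = 0
    while len(centers) < spec.n_aggregates:
        if tries >= max_tries:
            raise AggregatePlacementError(
                f"could not place {spec.n_aggregates} aggregates with "
                f"gap {spec.min_aggregate_gap_um} µm after {max_tries} tries"
            )
        tries += 1
        cand = lo + rng.random(2) * (hi - lo)
        if all(np.hypot(*(cand - c)) >= min_center_dist for c in centers):
            centers.append(cand)
    return np.array(centers).reshape(-1, 2)


def _fill_aggregate(
    center: np.ndarray, spec: SpatialSpec, rng: np.random.Generator
) -> np.ndarray:
    pts = [center.copy()]
    while len(pts) < spec.cells_per_aggregate:
        anchor = pts[int(rng.integers(len(pts)))]
        # uniform in a disk of radius _CHAIN_STEP_UM around the anchor
        while True:
            r = _CHAIN_STEP_UM * np.sqrt(rng.random())
            theta = 2.0 * np.pi * rng.random()
            cand = anchor + r * np.array([np.cos(theta), np.sin(theta)])
            if np.hypot(*(cand - center)) <= spec.aggregate_radius_um:
                pts.append(cand)
                break
    return np.array(pts)


def gen_spatial_tissue(spec: SpatialSpec) -> Tuple[pd.DataFrame, pd.Series]:
    """Generate (centroid table, ground-truth community labels).

    The centroid table has ``x_um``, ``y_um`` and one 0/1 column per marker;
    labels are ``aggregate_<i>`` for planted aggregate members and
    ``background`` otherwise, index-aligned with the table.
    """
    spec.validate()
    rng = _spawn_rng(spec.seed, "tissue")

    coords = []
    labels = []
    marker_rows = []

    centers = _place_centers(spec, rng)
    for i, center in enumerate(centers):
        pts = _fill_aggregate(center, spec, rng)
        for pt in pts:
            coords.append(pt)
            labels.append(f"aggregate_{i}")
            marker_rows.append(
                [int(rng.random() < spec.marker_probs_in_aggregate[m])
                 for m in SPATIAL_MARKERS]
            )

    area = spec.field_width_um * spec.field_height_um
    n_bg = int(rng.poisson(spec.background_density * area))
    for _ in range(n_bg):
        coords.append(rng.random(2) * np.array([spec.field_width_um, spec.field_height_um]))
        labels.append("background")
        marker_rows.append(
            [int(rng.random() < spec.marker_probs_background[m])
             for m in SPATIAL_MARKERS]
        )

    if coords:
        xy = np.array(coords)
        cells = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1]})
    else:
        cells = pd.DataFrame({"x_um": [], "y_um": []})
    markers = pd.DataFrame(marker_rows, columns=list(SPATIAL_MARKERS), dtype=int)
    cells = pd.concat([cells, markers], axis=1)
    return cells, pd.Series(labels, name="truth_community")
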