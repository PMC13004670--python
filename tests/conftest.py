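import numpy as np
import pandas as pd
import pytest

from humoralkit._constants import SPATIAL_MARKERS
from humoralkit.synthetic_data import CohortSpec, SpatialSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort_spec():
    return CohortSpec(
        n_patients_R=2, n_patients_NR=2, cells_per_sample=60,
        tissues=("tumor", "adjacent", "lymph_node"), seed=11,
    )


def make_cells(coords, **markers):
    """Spatial cell table from coordinate pairs; unspecified markers are 0."""
    coords = np.asarray(coords, dtype=float)
    df = pd.DataFrame({"x_um": coords[:, 0], "y_um": coords[:, 1]})
    n = len(df)
    for m in SPATIAL_MARKERS:
        value = markers.get(m, 0)
        df[m] = np.asarray(value, dtype=int) if np.ndim(value) else int(value)
    return df


@pytest.fixture
def separable_spatial_spec():
    """Aggregates whose seed-positive cells exactly match ground truth."""
    probs_in = {"CD3": 1.0, "CD8": 0.4, "CD20": 1.0, "CD68": 0.1,
                "FOXP3": 0.05, "MZB1": 0.3}
    probs_bg = {m: 0.0 for m in SPATIAL_MARKERS}
    return SpatialSpec(
        n_aggregates=3,
        marker_probs_in_aggregate=probs_in,
        marker_probs_background=probs_bg,
        min_aggregate_gap_um=50.0,
        seed=5,
    )


def brute_force_components(points, link_dist):
    """BFS connected components over the full pairwise distance matrix."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.hypot(points[:, None, 0] - points[None, :, 0],
                 points[:, None, 1] - points[None, :, 1])
    adj = d <= link_dist
    labels = -np.ones(n, dtype=int)
    current = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(adj[i]):
                if labels[j] < 0:
                    labels[j] = current
                    stack.append(j)
        current += 1
    return labels
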