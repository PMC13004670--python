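import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import brute_force_components, make_cells
from humoralkit import spatial
from humoralkit.synthetic_data import SpatialSpec, gen_spatial_tissue


def detected_labels(cells, communities):
    labels = np.full(len(cells), -1)
    for com in communities:
        labels[com.members] = com.community_id
    return labels


class TestDetectTlsCommunities:
    def test_hand_geometry_example(self):
        # 3 CD20+ cells chained 5 µm apart, 1 CD3+ cell 100 µm away
        cells = make_cells([(0, 0), (5, 0), (10, 0), (110, 0)],
                           CD20=[1, 1, 1, 0], CD3=[0, 0, 0, 1])
        coms = spatial.detect_tls_communities(cells, min_community_size=1)
        assert sorted(c.size for c in coms) == [1, 3]
        coms2 = spatial.detect_tls_communities(cells, min_community_size=2)
        assert [c.size for c in coms2] == [3]

    def test_marker_negative_cells_never_members(self, rng):
        xy = rng.random((60, 2)) * 50
        pos = rng.random(60) < 0.5
        cells = make_cells(xy, CD20=pos.astype(int))
        coms = spatial.detect_tls_communities(cells, min_community_size=1)
        members = np.concatenate([c.members for c in coms]) if coms else []
        assert set(members) <= set(np.flatnonzero(pos))

    def test_no_positive_cells_empty_list(self):
        cells = make_cells([(0, 0), (5, 5)])
        assert spatial.detect_tls_communities(cells) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_bfs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 300))
        xy = rng.random((n, 2)) * 120
        cells = make_cells(
            xy,
            CD20=(rng.random(n) < 0.4).astype(int),
            CD3=(rng.random(n) < 0.3).astype(int),
            CD8=(rng.random(n) < 0.2).astype(int),
        )
        coms = spatial.detect_tls_communities(cells, min_community_size=1)
        got = detected_labels(cells, coms)
        pos = cells[["CD3", "CD8", "CD20"]].any(axis=1).to_numpy()
        expected = brute_force_components(xy[pos], 10.0)
        assert adjusted_rand_score(expected, got[pos]) == 1.0
        assert (got[~pos] == -1).all()

    def test_recovers_generator_ground_truth(self, separable_spatial_spec):
        cells, truth = gen_spatial_tissue(separable_spatial_spec)
        coms = spatial.detect_tls_communities(cells)
        got = detected_labels(cells, coms)
        mask = (truth != "background").to_numpy()
        assert adjusted_rand_score(truth[mask], got[mask]) == 1.0


class TestRadialProfile:
    def test_ring_algebra(self):
        rng = np.random.default_rng(0)
        cells = make_cells(rng.random((40, 2)) * 100, CD20=1)
        com = spatial.SpatialCommunity(0, np.arange(40))
        spatial.radial_profile(com, cells)
        area = com.effective_area_um2
        r_eff = np.sqrt(area / np.pi)
        # r_k = R_eff * sqrt(k/10); disk areas are k/10 of the hull area
        for k in range(1, 10):
            assert com.ring_radii[k - 1] == pytest.approx(r_eff * np.sqrt(k / 10))
            assert np.pi * com.ring_radii[k - 1] ** 2 == pytest.approx(
                k / 10 * area, rel=1e-9)
        assert com.ring_radii[-1] >= r_eff

    def test_cumulative_counts_monotone(self, rng):
        cells = make_cells(rng.random((200, 2)) * 100,
                           CD20=(rng.random(200) < 0.5).astype(int),
                           MZB1=(rng.random(200) < 0.3).astype(int))
        com = spatial.SpatialCommunity(0, np.arange(200))
        spatial.radial_profile(com, cells)
        for counts in com.ring_cumulative_counts.values():
            assert (np.diff(counts) >= 0).all()

    def test_uniform_field_flat_profile(self):
        rng = np.random.default_rng(3)
        n = 5000
        cells = make_cells(rng.random((n, 2)) * 1000, MZB1=1, CD20=1)
        # a community in the center so rings stay inside the field
        center_mask = (np.hypot(cells["x_um"] - 500, cells["y_um"] - 500) < 150)
        com = spatial.SpatialCommunity(0, np.flatnonzero(center_mask))
        spatial.radial_profile(com, cells)
        dens = com.ring_cumulative_density["MZB1"]
        k = np.arange(1, 11)
        slope, _, _, p, _ = __import__("scipy.stats", fromlist=["linregress"]).linregress(k, dens)
        rel_drift = abs(dens[-1] - dens[0]) / dens.mean()
        assert p > 0.01 or rel_drift < 0.1

    def test_central_blob_strictly_decreasing(self):
        rng = np.random.default_rng(4)
        blob = rng.normal(500, 5, size=(100, 2))
        bg = rng.random((400, 2)) * 1000
        xy = np.vstack([blob, bg])
        mzb1 = np.r_[np.ones(100), np.zeros(400)]
        cd20 = np.r_[np.ones(100), (rng.random(400) < 0.5)]
        cells = make_cells(xy, MZB1=mzb1.astype(int), CD20=cd20.astype(int))
        members = np.flatnonzero(np.hypot(xy[:, 0] - 500, xy[:, 1] - 500) < 100)
        com = spatial.SpatialCommunity(0, members)
        spatial.radial_profile(com, cells)
        dens = com.ring_cumulative_density["MZB1"]
        assert (np.diff(dens) < 0).all()

    def test_degenerate_collinear_hull_falls_back(self):
        cells = make_cells([(0, 0), (10, 0), (20, 0), (30, 0)], CD20=1)
        com = spatial.SpatialCommunity(0, np.arange(4))
        spatial.radial_profile(com, cells)  # must not raise
        assert com.effective_area_um2 > 0

    def test_requires_three_members(self):
        cells = make_cells([(0, 0), (1, 1)], CD20=1)
        with pytest.raises(ValueError):
            spatial.radial_profile(spatial.SpatialCommunity(0, np.arange(2)), cells)


class TestAggregateEnrichment:
    def test_single_disk_area(self):
        cells = make_cells([(50, 50)], MZB1=1)
        _, aggs = spatial.aggregate_enrichment(cells, ["MZB1"], radius_um=10)
        assert aggs.iloc[0]["area_um2"] == pytest.approx(np.pi * 100, rel=1e-3)

    def test_two_disk_lens_area(self):
        r, d = 10.0, 10.0
        cells = make_cells([(0, 0), (d, 0)], MZB1=1)
        _, aggs = spatial.aggregate_enrichment(cells, ["MZB1"], radius_um=r)
        assert len(aggs) == 1
        # union = 2*pi*r^2 - lens; lens = 2 r^2 cos^-1(d/2r) - d/2 sqrt(4r^2-d^2)
        lens = 2 * r ** 2 * np.arccos(d / (2 * r)) - d / 2 * np.sqrt(4 * r ** 2 - d ** 2)
        expected = 2 * np.pi * r ** 2 - lens
        assert aggs.iloc[0]["area_um2"] == pytest.approx(expected, rel=1e-3)
        assert aggs.iloc[0]["area_um2"] < 2 * np.pi * r ** 2

    def test_uniform_phenotype_enrichment_near_one(self):
        rng = np.random.default_rng(8)
        n = 5000
        xy = rng.random((n, 2)) * 1000
        # query cells are disk centers and hence inside by construction, so
        # the uniform phenotype must live on the non-query cells
        query = rng.random(n) < 0.2
        pheno = (~query) & (rng.random(n) < 0.3)
        cells = make_cells(xy, CD20=query.astype(int), CD68=pheno.astype(int))
        enr, _ = spatial.aggregate_enrichment(cells, ["CD20"], radius_um=10)
        val = enr.set_index("phenotype").at["CD68+", "enrichment"]
        assert 0.8 < val < 1.25

    def test_query_marker_count_bounds(self):
        cells = make_cells([(0, 0)], MZB1=1)
        with pytest.raises(ValueError):
            spatial.aggregate_enrichment(cells, [])
        with pytest.raises(ValueError):
            spatial.aggregate_enrichment(cells, ["CD3", "CD8", "CD20", "MZB1"])

    def test_no_reference_cells_empty(self):
        cells = make_cells([(0, 0)], CD68=1)
        enr, aggs = spatial.aggregate_enrichment(cells, ["MZB1"])
        assert enr.empty and aggs.empty


class TestInfiltrationScores:
    def test_all_positive_scores_one(self, rng):
        cells = make_cells(rng.random((80, 2)) * 100, MZB1=1)
        scores, mean = spatial.infiltration_scores(cells, k=10)
        assert (scores["infiltration_score"] == 1.0).all()
        assert mean == 1.0

    def test_iid_labels_calibrated(self):
        rng = np.random.default_rng(11)
        p = 0.3
        means = []
        for _ in range(10):
            cells = make_cells(rng.random((400, 2)) * 500,
                               MZB1=(rng.random(400) < p).astype(int))
            _, m = spatial.infiltration_scores(cells, k=10)
            means.append(m)
        assert abs(np.mean(means) - p) < 0.05

    def test_two_blobs_half_and_zero(self):
        rng = np.random.default_rng(12)
        blob1 = rng.normal(0, 10, size=(200, 2))
        blob2 = rng.normal(0, 10, size=(200, 2)) + 2000
        mzb1 = np.r_[(rng.random(200) < 0.5).astype(int), np.zeros(200, dtype=int)]
        cells = make_cells(np.vstack([blob1, blob2]), MZB1=mzb1)
        scores, mean = spatial.infiltration_scores(cells, k=10)
        # communities nest within blobs, so the unweighted mean sits near
        # (0.5 + 0.0) / 2
        assert abs(mean - 0.25) < 0.08

    def test_translation_rotation_invariance(self, rng):
        xy = rng.random((150, 2)) * 200
        mzb1 = (rng.random(150) < 0.4).astype(int)
        cells = make_cells(xy, MZB1=mzb1)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        cells2 = make_cells(xy @ rot.T + [1000, -500], MZB1=mzb1)
        s1, m1 = spatial.infiltration_scores(cells, k=10, seed=0)
        s2, m2 = spatial.infiltration_scores(cells2, k=10, seed=0)
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_seed_reproducible(self, rng):
        cells = make_cells(rng.random((200, 2)) * 300,
                           MZB1=(rng.random(200) < 0.3).astype(int))
        s1, _ = spatial.infiltration_scores(cells, k=10, seed=0)
        s2, _ = spatial.infiltration_scores(cells, k=10, seed=0)
        pd.testing.assert_frame_equal(s1, s2)

    def test_k_too_large_raises(self):
        cells = make_cells([(0, 0), (1, 1)], MZB1=1)
        with pytest.raises(ValueError, match="smaller"):
            spatial.infiltration_scores(cells, k=10)

    def test_mixed_aggregates_score_higher_than_excluded(self):
        # responder-like: MZB1+ cells interleaved in the aggregates;
        # non-responder-like: identical layout with MZB1 excluded from the
        # aggregates (background rate unchanged)
        higher = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            centers = rng.random((4, 2)) * 800 + 100
            pts = np.vstack([c + rng.normal(0, 15, size=(80, 2)) for c in centers])
            bg = rng.random((150, 2)) * 1000
            xy = np.vstack([pts, bg])
            bg_mzb1 = (rng.random(150) < 0.05).astype(int)
            mixed = np.r_[(rng.random(len(pts)) < 0.4).astype(int), bg_mzb1]
            excluded = np.r_[np.zeros(len(pts), dtype=int), bg_mzb1]
            _, m_mixed = spatial.infiltration_scores(make_cells(xy, MZB1=mixed), k=10)
            _, m_excl = spatial.infiltration_scores(make_cells(xy, MZB1=excluded), k=10)
            higher += m_mixed > m_excl
        assert higher == 5
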