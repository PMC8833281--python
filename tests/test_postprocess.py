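"""Candidate detection, refinement, linking, jump correction, stop rule,
modality fusion, and full path reconstruction."""

import numpy as np
import pytest

from cathrecon.phantom import rasterize_truth_mask
from cathrecon.pipeline import geometry_from_truth
from cathrecon.postprocess import (
    Candidate,
    CatheterPath,
    TemplateGeometry,
    compute_stop_slice,
    correct_jumping,
    find_candidates,
    link_next_slice,
    merge_modalities,
    reconstruct,
    refine_in_rectangle,
    refine_region_centroid,
)


class TestFindCandidates:
    def test_square_block_centroid(self):
        sl = np.zeros((20, 20))
        sl[9:12, 9:12] = 1
        (c,) = find_candidates(sl)
        assert c.centroid == (10.0, 10.0)
        assert c.size == 9

    def test_two_separated_components(self):
        sl = np.zeros((20, 20))
        sl[2:4, 2:4] = 1
        sl[10:12, 10:12] = 1
        assert len(find_candidates(sl)) == 2

    def test_l_shape_centroid_matches_hand_enumeration(self):
        sl = np.zeros((10, 10))
        voxels = [(2, 2), (3, 2), (4, 2), (4, 3), (4, 4)]
        for r, c in voxels:
            sl[r, c] = 1
        (cand,) = find_candidates(sl)
        expect = np.mean(voxels, axis=0)  # brute-force mean of coordinates
        assert np.allclose(cand.centroid, expect)

    def test_diagonal_voxels_are_one_component(self):
        # 8-connectivity joins diagonal neighbors
        sl = np.zeros((8, 8))
        sl[2, 2] = sl[3, 3] = 1
        assert len(find_candidates(sl)) == 1

    def test_min_size_filter_and_empty_slice(self):
        sl = np.zeros((10, 10))
        sl[1, 1] = 1
        sl[5:8, 5:8] = 1
        assert len(find_candidates(sl, min_size=2)) == 1
        assert find_candidates(np.zeros((5, 5))) == []


class TestRefine:
    def test_unique_maximum_found(self):
        sl = np.zeros((20, 20))
        sl[5, 7] = 3.0
        assert refine_in_rectangle(sl, (6.0, 6.0), 5, "t1w") == (5, 7)

    def test_t2w_on_negated_image_matches_t1w(self, rng):
        sl = rng.normal(size=(30, 30))
        a = refine_in_rectangle(sl, (15.0, 15.0), 5, "t1w")
        b = refine_in_rectangle(-sl, (15.0, 15.0), 5, "t2w")
        assert a == b

    def test_uniform_window_returns_approx_position(self):
        sl = np.full((20, 20), 2.5)
        assert refine_in_rectangle(sl, (9.0, 11.0), 4, "t1w") == (9, 11)

    def test_tie_broken_by_distance_then_row_major(self):
        sl = np.zeros((20, 20))
        sl[6, 10] = sl[10, 6] = 5.0  # equidistant from (8, 8)
        assert refine_in_rectangle(sl, (8.0, 8.0), 6, "t1w") == (6, 10)
        sl2 = np.zeros((20, 20))
        sl2[6, 8] = sl2[10, 8] = 5.0  # (6,8) and (10,8) equidistant from (8,8)
        assert refine_in_rectangle(sl2, (8.0, 8.0), 6, "t1w") == (6, 8)

    def test_degenerate_rectangle_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            refine_in_rectangle(np.zeros((10, 10)), (-50.0, -50.0), 2, "t1w")

    def test_region_centroid_recovers_disk_center_under_noise(self, rng):
        rr, cc = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        d = np.hypot(rr - 14.3, cc - 16.7)
        sl = 4.0 * np.clip(2.5 - d, 0, 1) + rng.normal(0, 0.4, (30, 30))
        r, c = refine_region_centroid(sl, (14.0, 17.0), 5, "t1w")
        assert np.hypot(r - 14.3, c - 16.7) < 0.6
        r2, c2 = refine_region_centroid(-sl, (14.0, 17.0), 5, "t2w")
        assert np.hypot(r2 - 14.3, c2 - 16.7) < 0.6


def _brute_force_greedy(positions, candidates, nbhd):
    """Independent matching oracle: repeatedly take the globally closest
    admissible catheter-candidate pair."""
    assignments = {}
    used = set()
    while True:
        best = None
        for cid, (r, c) in positions.items():
            if cid in assignments:
                continue
            for j, cand in enumerate(candidates):
                if j in used:
                    continue
                d = np.hypot(cand.centroid[0] - r, cand.centroid[1] - c)
                if d > nbhd:
                    continue
                key = (d, cid, j)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, cid, j = best
        assignments[cid] = j
        used.add(j)
    jumped = [cid for cid in positions if cid not in assignments]
    return assignments, jumped


class TestLinking:
    def test_exact_candidates_give_identity_assignment(self):
        pos = {0: (5.0, 5.0), 1: (15.0, 15.0)}
        cands = [Candidate(1, (5.0, 5.0)), Candidate(1, (15.0, 15.0))]
        a, jumped = link_next_slice(pos, cands)
        assert jumped == []
        assert a[0].centroid == (5.0, 5.0)
        assert a[1].centroid == (15.0, 15.0)

    def test_no_candidates_means_all_jumped(self):
        pos = {0: (5.0, 5.0), 1: (15.0, 15.0)}
        a, jumped = link_next_slice(pos, [])
        assert a == {}
        assert sorted(jumped) == [0, 1]

    def test_candidate_serves_at_most_one_catheter(self):
        pos = {0: (5.0, 5.0), 1: (6.0, 5.0)}
        cands = [Candidate(1, (5.4, 5.0))]
        a, jumped = link_next_slice(pos, cands)
        assert list(a) == [0]  # closer catheter wins
        assert jumped == [1]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n_cath = int(rng.integers(1, 11))
            n_cand = int(rng.integers(0, 21))
            pos = {i: tuple(rng.uniform(0, 30, 2)) for i in range(n_cath)}
            cands = [Candidate(1, tuple(rng.uniform(0, 30, 2))) for _ in range(n_cand)]
            a, jumped = link_next_slice(pos, cands, neighborhood_px=8.0)
            ea, ej = _brute_force_greedy(pos, cands, 8.0)
            assert {cid: cands.index(c) for cid, c in a.items()} == ea
            assert sorted(jumped) == sorted(ej)

    def test_requires_at_least_one_catheter(self):
        with pytest.raises(ValueError):
            link_next_slice({}, [])


class TestJumpCorrection:
    def test_worked_example(self):
        # detected moves (10,10)->(11,12) and (20,20)->(21,22): dx=1, dy=2
        out = correct_jumping(
            [[10, 10], [20, 20]], [[11, 12], [21, 22]], [[5, 5]]
        )
        assert np.allclose(out, [[6.0, 7.0]])

    def test_stationary_catheters_leave_jumped_unchanged(self):
        out = correct_jumping([[3, 4], [8, 9]], [[3, 4], [8, 9]], [[1, 1]])
        assert np.allclose(out, [[1.0, 1.0]])

    def test_absolute_values_do_not_cancel(self):
        # signed displacements +1 and -1 average to 0, absolute form gives 1
        out = correct_jumping([[0, 0], [0, 0]], [[1, 0], [-1, 0]], [[5, 5]])
        assert np.allclose(out, [[6.0, 5.0]])
        signed = correct_jumping(
            [[0, 0], [0, 0]], [[1, 0], [-1, 0]], [[5, 5]], signed=True
        )
        assert np.allclose(signed, [[5.0, 5.0]])

    def test_zero_detected_catheters_rejected(self):
        with pytest.raises(ValueError):
            correct_jumping(np.empty((0, 2)), np.empty((0, 2)), [[1, 1]])

    def test_translation_consistency(self, rng):
        """Uniform non-negative translation of detected catheters corrects a
        jumped catheter by exactly that translation."""
        for _ in range(50):
            k = int(rng.integers(1, 8))
            prev = rng.uniform(0, 50, (k, 2))
            d = rng.uniform(0, 3, 2)  # non-negative components
            out = correct_jumping(prev, prev + d, [[10.0, 10.0]])
            assert np.allclose(out, [10.0 + d[0], 10.0 + d[1]])


class TestStopRule:
    def test_clinical_length_example(self):
        geo = TemplateGeometry(294.0, 100.0, 20.0, 4, [[10, 10]])
        assert compute_stop_slice(geo, 1.0) == [4 + 174]

    def test_zero_insertion_stays_on_seed_slice(self):
        geo = TemplateGeometry(294.0, 274.0, 20.0, 6, [[10, 10]])
        assert compute_stop_slice(geo, 1.0) == [6]

    def test_two_mm_slices(self):
        geo = TemplateGeometry(294.0, 100.0, 20.0, 0, [[10, 10]])
        assert compute_stop_slice(geo, 2.0) == [87]

    def test_matches_integer_arithmetic_on_random_geometries(self, rng):
        for _ in range(1000):
            total = float(rng.integers(100, 400))
            template = float(rng.integers(0, 30))
            free = float(rng.integers(0, int(total - template)))
            thick = float(rng.choice([0.5, 1.0, 2.0, 2.5]))
            m = int(rng.integers(0, 10))
            geo = TemplateGeometry(total, free, template, m, [[5, 5]])
            expect = m + int((total - (free + template)) // thick)
            assert compute_stop_slice(geo, thick)[0] == expect

    def test_invalid_thickness_and_geometry_rejected(self):
        geo = TemplateGeometry(100.0, 90.0, 5.0, 0, [[1, 1]])
        with pytest.raises(ValueError, match="positive"):
            compute_stop_slice(geo, 0.0)
        # free + template exceeding total is impossible physically
        with pytest.raises(ValueError):
            TemplateGeometry(100.0, 99.0, 5.0, 0, [[1, 1]])


class TestMergeModalities:
    def test_identical_sets_fully_fused(self):
        a = [Candidate(1, (5.0, 5.0), "t1w"), Candidate(1, (9.0, 9.0), "t1w")]
        b = [Candidate(1, (5.0, 5.0), "t2w"), Candidate(1, (9.0, 9.0), "t2w")]
        out = merge_modalities(a, b, 2.0)
        assert len(out) == 2
        assert all(c.dual for c in out)

    def test_disjoint_sets_concatenated(self):
        a = [Candidate(1, (1.0, 1.0), "t1w")]
        b = [Candidate(1, (20.0, 20.0), "t2w")]
        out = merge_modalities(a, b, 2.0)
        assert len(out) == 2
        assert not any(c.dual for c in out)

    def test_nearby_pair_merges_to_mean(self):
        a = [Candidate(1, (10.0, 10.0), "t1w")]
        b = [Candidate(1, (11.0, 11.0), "t2w")]
        (c,) = merge_modalities(a, b, 2.0)
        assert c.centroid == (10.5, 10.5)
        assert c.dual


def _straight_setup(n_cath=3, n_slices=12, radius=1.5):
    """Straight vertical catheters rendered directly into masks."""
    shape = (40, 40, n_slices)
    cols = [8 + 10 * i for i in range(n_cath)]
    paths = [
        CatheterPath(i, 0, np.tile([20.0, c], (n_slices, 1)))
        for i, c in enumerate(cols)
    ]
    masks = rasterize_truth_mask(paths, shape, radius=radius)
    geo = TemplateGeometry(
        total_length_mm=np.full(n_cath, 294.0),
        free_length_mm=np.full(n_cath, 294.0 - 20.0 - (n_slices - 1)),
        template_thickness_mm=20.0,
        start_slice=0,
        seeds=np.array([[20.0, c] for c in cols], dtype=float),
    )
    return shape, paths, masks, geo


class TestReconstruct:
    def test_straight_catheters_stay_constant(self):
        shape, truth, masks, geo = _straight_setup()
        rec = reconstruct(None, None, masks, None, geo, refine_mode=None)
        assert len(rec) == 3
        for p, t in zip(rec, truth):
            assert len(p.points) == shape[2]
            assert np.allclose(p.points, t.points)

    def test_oracle_masks_recover_phantom_paths_within_one_voxel(
        self, small_phantom, small_phantom_masks, small_geometry
    ):
        cfg, t1w, t2w, truth = small_phantom
        rec = reconstruct(
            t1w, t2w, small_phantom_masks, small_phantom_masks.copy(), small_geometry
        )
        assert len(rec) == len(truth)
        for p, t in zip(rec, truth):
            assert len(p.points) == len(t.points)
            assert np.abs(p.points - t.points).max() < 1.0

    def test_single_slice_dropout_yields_one_jump_corrected_point(self):
        shape, truth, masks, geo = _straight_setup()
        s_drop, cath = 6, 1
        masks = masks.copy()
        masks[:, :, s_drop][:, 14:23] = False  # erase catheter 1 (col 18) only
        rec = reconstruct(None, None, masks, None, geo, refine_mode=None)
        p = rec[cath]
        assert len(p.points) == shape[2]
        assert p.provenance.count("jump-corrected") == 1
        assert p.provenance[s_drop] == "jump-corrected"
        # detected catheters were stationary, so the imputed point is unchanged
        assert np.allclose(p.points[s_drop], truth[cath].points[s_drop])

    def test_fully_empty_slice_carries_all_positions_over(self):
        shape, truth, masks, geo = _straight_setup()
        masks = masks.copy()
        masks[:, :, 4] = False
        rec = reconstruct(None, None, masks, None, geo, refine_mode=None)
        for p, t in zip(rec, truth):
            assert len(p.points) == shape[2]
            assert p.provenance[4] == "jump-corrected"
            assert np.allclose(p.points, t.points)

    def test_path_completeness_under_random_masks(self, rng):
        """|paths| == |seeds| and full slice coverage for arbitrary masks."""
        shape = (32, 32, 10)
        geo = TemplateGeometry(
            total_length_mm=np.full(4, 294.0),
            free_length_mm=np.full(4, 294.0 - 20.0 - 9.0),
            template_thickness_mm=20.0,
            start_slice=0,
            seeds=np.array([[8, 8], [8, 24], [24, 8], [24, 24]], dtype=float),
        )
        for _ in range(10):
            masks = rng.random(shape) > 0.995
            rec = reconstruct(None, None, masks, None, geo, refine_mode=None)
            assert len(rec) == 4
            for p in rec:
                assert len(p.points) == 10
                assert list(p.slices) == list(range(10))
                assert p.provenance[0] == "seed"

    def test_zero_seeds_rejected(self):
        with pytest.raises(ValueError):
            TemplateGeometry(294.0, 100.0, 20.0, 0, np.empty((0, 2)))

    def test_volume_not_covering_implant_rejected(self):
        shape, truth, masks, geo = _straight_setup(n_slices=5)
        geo2 = TemplateGeometry(
            geo.total_length_mm, geo.free_length_mm - 30.0,
            geo.template_thickness_mm, 0, geo.seeds,
        )
        with pytest.raises(ValueError, match="slice"):
            reconstruct(None, None, masks, None, geo2, refine_mode=None)
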