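"""Per-slice micro-CT stages: preprocessing, EnFCM, thresholds, decision
tree, spot detection/selection/regularization."""
import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk as disk_se

from canaliz import mct_slice, phantom
from canaliz.mct_slice import (
    DecisionTree,
    SliceImage,
    choose_partition,
    detect_spots,
    enfcm_histogram,
    estimate_global_threshold,
    gray_histogram,
    partition_slice,
    preprocess_slice,
    regularize_spots,
    select_spots,
    spot_center_from_mask,
    train_partition_tree,
)
from conftest import disk_mask


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_constant_image_passthrough(self):
        img = np.full((20, 20), 37.0)
        out = preprocess_slice(img, median_radius=1)
        assert out.roi_offset == (0, 0)
        assert np.allclose(out.pixels, 37.0)

    def test_salt_pixel_replaced_by_median(self):
        img = np.full((15, 15), 50.0)
        img[7, 7] = 250.0
        out = preprocess_slice(img, median_radius=1, remove_text=False,
                               content_tol=0.01)
        r, c = out.roi_offset
        assert out.pixels[7 - r, 7 - c] == 50.0

    def test_roi_equals_phantom_interior(self):
        # bright 28x24 block with a 10-pixel dark margin all around
        img = np.full((48, 44), 10.0)
        img[10:38, 10:34] = 180.0
        out = preprocess_slice(img, median_radius=0)
        assert out.roi_offset == (10, 10)
        assert out.pixels.shape == (28, 24)

    def test_all_background_slice_skipped(self):
        img = np.full((20, 20), 10.0)
        img[3, 3] = 10.5  # negligible texture, below the content threshold
        assert preprocess_slice(img, median_radius=0, remove_text=False) is None

    def test_corner_text_removed(self):
        spec = phantom.preset("straight", shape=(6, 64, 64), canal_radius=4.0)
        model = phantom.IntensityModel.microct_default(noise_sd=0.0,
                                                       ring_amplitude=0.0,
                                                       text_glyphs=True)
        vol, _ = phantom.render_microct_stack(spec, shape=(6, 64, 64), model=model)
        raw = vol.voxels[3]
        assert (raw > 230).any()  # glyphs are present in the raw slice
        out = preprocess_slice(raw, median_radius=0)
        assert not (out.pixels > 230).any()


# ---------------------------------------------------------------------------
# EnFCM
# ---------------------------------------------------------------------------

def per_pixel_fcm(pixels, c, m=2.0, tol=1e-4, max_iter=500):
    """Independent per-pixel FCM oracle (no histogram weighting)."""
    x = np.asarray(pixels, dtype=float).ravel()
    q = (np.arange(c) + 0.5) / c
    v = np.quantile(x, q)
    for i in range(1, c):
        if v[i] <= v[i - 1]:
            v[i] = v[i - 1] + 1e-6
    for _ in range(max_iter):
        d2 = (x[None, :] - v[:, None]) ** 2
        zero = d2 < 1e-300
        with np.errstate(divide="ignore"):
            p = d2 ** (-1.0 / (m - 1.0))
        p[zero] = 0.0
        u = p / np.maximum(p.sum(axis=0, keepdims=True), 1e-300)
        for k in np.where(zero.any(axis=0))[0]:
            u[:, k] = 0.0
            u[int(np.argmax(zero[:, k])), k] = 1.0
        w = u ** m
        v_new = (w @ x) / np.maximum(w.sum(axis=1), 1e-300)
        if np.max(np.abs(v_new - v)) < tol:
            v = v_new
            break
        v = v_new
    return np.sort(v)


class TestEnfcm:
    def test_two_delta_peaks(self):
        res = enfcm_histogram([10.0, 200.0], [500, 500], c=2)
        assert np.allclose(res.prototypes, [10.0, 200.0], atol=0.01)

    def test_four_delta_peaks(self):
        levels = [15.0, 25.0, 160.0, 205.0]
        res = enfcm_histogram(levels, [100, 40, 800, 200], c=4)
        assert np.allclose(res.prototypes, levels, atol=0.1)

    def test_prototypes_strictly_ascending(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(64, 64))
        levels, counts = gray_histogram(img)
        res = enfcm_histogram(levels, counts, c=4)
        assert np.all(np.diff(res.prototypes) > 0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            enfcm_histogram([10.0, 20.0, 30.0], [5, 5, 5], c=4)

    def test_matches_per_pixel_fcm_on_two_gaussian_image(self):
        rng = np.random.default_rng(3)
        img = np.round(np.concatenate([
            rng.normal(60, 10, 2048), rng.normal(180, 10, 2048)
        ]).clip(0, 255)).reshape(64, 64)
        levels, counts = gray_histogram(img)
        res = enfcm_histogram(levels, counts, c=2)
        oracle = per_pixel_fcm(img, c=2)
        assert np.max(np.abs(res.prototypes - oracle)) < 0.5

    @pytest.mark.parametrize("c", [2, 3, 4])
    def test_histogram_equals_per_pixel_on_random_images(self, c):
        rng = np.random.default_rng(100 + c)
        for _ in range(3):
            img = np.round(rng.uniform(0, 255, size=(32, 32)))
            levels, counts = gray_histogram(img)
            res = enfcm_histogram(levels, counts, c=c)
            oracle = per_pixel_fcm(img, c=c)
            assert np.max(np.abs(res.prototypes - oracle)) < 0.5


# ---------------------------------------------------------------------------
# global threshold and double partitioning
# ---------------------------------------------------------------------------

def _slice(arr, z=0):
    return SliceImage(pixels=np.asarray(arr, dtype=float), roi_offset=(0, 0),
                      z_index=z)


class TestGlobalThreshold:
    def test_full_fraction_uses_all_slices(self):
        s1 = _slice(np.full((8, 8), 20.0))
        s2 = _slice(np.full((8, 8), 200.0))
        tau = estimate_global_threshold([s1, s2], sample_fraction=1.0)
        assert tau == pytest.approx(110.0, abs=1.0)

    def test_two_percent_of_100_slices_takes_endpoints(self):
        # ceil(0.02 * 100) = 2 slices at linearly spaced indices 0 and 99;
        # all other slices are degenerate and would break EnFCM if touched
        good = np.zeros((4, 4))
        good[:2] = 200.0
        slices = [_slice(good)] + [_slice(np.full((4, 4), 99.0))] * 98 + [_slice(good)]
        tau = estimate_global_threshold(slices, sample_fraction=0.02)
        assert tau == pytest.approx(100.0, abs=1.0)

    def test_separates_canal_from_dentin_on_phantom(self, straight_mct):
        _, vol, truth = straight_mct
        slices = [preprocess_slice(raw, median_radius=1, z_index=z)
                  for z, raw in enumerate(vol.voxels)]
        tau = estimate_global_threshold([s for s in slices if s is not None])
        dark_true = truth.canal_mask | ~truth.tooth_mask
        mis = (vol.voxels < tau) != dark_true
        assert mis.mean() < 0.01


class TestPartitionSlice:
    def test_argmax_gap_rule_hand_evaluated(self):
        # prototypes (20, 60, 180, 210): maximal gap 60..180 -> i=2,
        # tau_local = 120 (midpoint convention)
        counts = {20: 500, 60: 300, 180: 900, 210: 250}
        img = np.concatenate([np.full(n, v, dtype=float)
                              for v, n in counts.items()])
        part, feats = partition_slice(_slice(img.reshape(-1, 10)), tau_global=100.0)
        assert feats.argmax_index == 2
        assert feats.tau_local == pytest.approx(120.0, abs=1.0)
        assert np.allclose(feats.tau_gaps, [20.0, 60.0, 15.0], atol=1.0)

    def test_all_dark_global_partition(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        part, _ = partition_slice(_slice(img), tau_global=100.0)
        assert part.binary_global.all()

    def test_degenerate_histogram_falls_back_to_global(self):
        img = np.full((8, 8), 42.0)
        part, feats = partition_slice(_slice(img), tau_global=100.0)
        assert part.degenerate
        assert part.chosen == "global"

    def test_noiseless_phantom_partitions_agree_with_truth(self):
        spec = phantom.preset("straight", shape=(12, 48, 48), canal_radius=4.0)
        model = phantom.IntensityModel.microct_default(noise_sd=0.0,
                                                       ring_amplitude=0.0)
        vol, truth = phantom.render_microct_stack(spec, shape=(12, 48, 48),
                                                  model=model)
        z = 6
        s = preprocess_slice(vol.voxels[z], median_radius=0)
        r0, c0 = s.roi_offset
        h, w = s.pixels.shape
        tau = estimate_global_threshold([s], sample_fraction=1.0)
        part, _ = partition_slice(s, tau)
        dark_true = (truth.canal_mask[z] | ~truth.tooth_mask[z])[r0:r0 + h,
                                                                 c0:c0 + w]
        assert np.array_equal(part.binary_local, dark_true)
        assert np.array_equal(part.binary_global, dark_true)


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

class TestDecisionTree:
    def test_single_class_is_single_leaf(self):
        rng = np.random.default_rng(1)
        samples = [(rng.uniform(0, 1, 4), "local") for _ in range(10)]
        tree = train_partition_tree(samples)
        assert tree.depth() == 0
        assert tree.predict(np.zeros(4)) == "local"

    def test_1d_separable_single_split(self):
        xs = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        samples = [(np.array([x, 0.0, 0.0, 0.0]),
                    "local" if x < 0.5 else "global") for x in xs]
        tree = train_partition_tree(samples)
        assert tree.depth() == 1
        assert tree.root.feature == 0
        assert 0.3 < tree.root.threshold < 0.7

    def test_homogeneous_leaves_zero_training_error(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(200, 4))
        y = np.where((X[:, 1] > 0.4) ^ (X[:, 3] > 0.6), "local", "global")
        samples = list(zip(X, y))
        tree = train_partition_tree(samples)
        assert all(tree.predict(f) == lab for f, lab in samples)

    def test_root_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, size=(200, 4))
        y = np.where(X[:, 2] + 0.1 * rng.standard_normal(200) > 0.5,
                     "local", "global")
        tree = train_partition_tree(list(zip(X, y)))

        # exhaustive oracle over all midpoint candidates on all 4 features
        def entropy(lab):
            _, cnt = np.unique(lab, return_counts=True)
            p = cnt / cnt.sum()
            return -(p * np.log2(p)).sum()

        best_gain = -1.0
        h0 = entropy(y)
        for f in range(4):
            vals = np.sort(np.unique(X[:, f]))
            for t in (vals[:-1] + vals[1:]) / 2:
                mask = X[:, f] <= t
                g = h0 - (mask.sum() * entropy(y[mask])
                          + (~mask).sum() * entropy(y[~mask])) / len(y)
                best_gain = max(best_gain, g)
        assert tree.root.gain == pytest.approx(best_gain, abs=1e-9)

    def test_agrees_with_sklearn_root_feature(self):
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(13)
        X = rng.uniform(0, 1, size=(150, 4))
        y = np.where(X[:, 1] > 0.55, "local", "global")
        tree = train_partition_tree(list(zip(X, y)))
        sk = DecisionTreeClassifier(criterion="entropy").fit(X, y)
        assert tree.root.feature == sk.tree_.feature[0]

    def test_contradictory_duplicates_rejected(self):
        v = np.array([0.5, 0.5, 0.5, 0.5])
        samples = [(v, "local"), (v.copy(), "global"), (np.ones(4), "local")]
        with pytest.raises(ValueError, match="contradictory"):
            train_partition_tree(samples)


class TestChoosePartition:
    def _partition(self, dark_local, dark_global, shape=(20, 20)):
        bl = np.zeros(shape, bool)
        bg = np.zeros(shape, bool)
        bl[5:5 + dark_local[0], 5:5 + dark_local[1]] = True
        bg[5:5 + dark_global[0], 5:5 + dark_global[1]] = True
        return mct_slice.SlicePartition(labeled4=np.zeros(shape, int),
                                        binary_local=bl, binary_global=bg)

    def _features(self):
        return mct_slice.ThresholdFeatures(tau_global=100.0,
                                           tau_gaps=np.array([1.0, 50.0, 5.0]),
                                           tau_local=120.0, argmax_index=2)

    def test_constant_tree_always_local(self):
        tree = train_partition_tree([(np.zeros(4), "local"),
                                     (np.ones(4), "local")])
        part = choose_partition(self._partition((3, 3), (9, 9)),
                                self._features(), tree)
        assert part.chosen == "local"
        assert part.decision_source == "tree"

    def test_hand_built_two_node_tree_traversal(self):
        from canaliz.mct_slice import _TreeNode
        tree = DecisionTree(root=_TreeNode(
            feature=0, threshold=100.0,
            left=_TreeNode(label="global"),
            right=_TreeNode(feature=2, threshold=25.0,
                            left=_TreeNode(label="local"),
                            right=_TreeNode(label="global"))))
        f = self._features()  # tau_global=100 <= 100 -> left -> global
        assert tree.predict(f) == "global"
        f2 = mct_slice.ThresholdFeatures(tau_global=150.0,
                                         tau_gaps=np.array([10.0, 20.0, 1.0]),
                                         tau_local=1.0, argmax_index=2)
        assert tree.predict(f2) == "local"  # right then gap 20 <= 25

    def test_heuristic_prefers_plausible_dark_fraction(self):
        # local partition has a plausible interior spot; global is empty
        part = choose_partition(self._partition((3, 3), (0, 0)),
                                self._features(), tree=None)
        assert part.chosen == "local"
        assert part.decision_source == "heuristic"

    def test_heuristic_trained_on_phantom_battery(self):
        """Tree trained on synthetic labeled features decides held-out
        samples correctly (>= 99%)."""
        rng = np.random.default_rng(5)
        # labels: local correct when the histogram is 4-modal -> large
        # middle gap; global otherwise
        def make(n):
            out = []
            for _ in range(n):
                four_modal = rng.random() < 0.5
                mid = rng.uniform(40, 80) if four_modal else rng.uniform(0, 8)
                feats = np.array([rng.uniform(80, 120), rng.uniform(0, 10),
                                  mid, rng.uniform(0, 10)])
                out.append((feats, "local" if four_modal else "global"))
            return out

        train, held = make(250), make(400)
        tree = train_partition_tree(train)
        acc = np.mean([tree.predict(f) == lab for f, lab in held])
        assert acc >= 0.99


# ---------------------------------------------------------------------------
# spots
# ---------------------------------------------------------------------------

class TestDetectSpots:
    def test_all_light_empty(self):
        assert detect_spots(np.zeros((8, 8), bool)) == []

    def test_interior_square(self):
        img = np.zeros((8, 8), bool)
        img[3:5, 4:6] = True
        (spot,) = detect_spots(img)
        assert spot.area == 4
        assert spot.center == (3.5, 4.5)

    def test_border_frame_discarded_as_outer_space(self):
        img = np.zeros((12, 12), bool)
        img[0, :] = img[-1, :] = img[:, 0] = img[:, -1] = True
        img[5:7, 5:7] = True
        spots = detect_spots(img)
        assert len(spots) == 1
        assert spots[0].area == 4

    def test_sorted_by_descending_area(self):
        img = np.zeros((20, 30), bool)
        img[2:4, 2:4] = True           # 4 px
        img[10:16, 10:16] = True       # 36 px
        img[5:7, 20:25] = True         # 10 px
        areas = [s.area for s in detect_spots(img)]
        assert areas == [36, 10, 4]

    def test_permutation_invariance(self):
        # the component set is intrinsic: flipping the image flips the
        # spots but never changes their number or areas
        rng = np.random.default_rng(2)
        img = rng.random((24, 24)) < 0.3
        img[0, :] = img[-1, :] = img[:, 0] = img[:, -1] = False
        a = sorted(s.area for s in detect_spots(img))
        b = sorted(s.area for s in detect_spots(img[::-1, ::-1]))
        assert a == b


class TestSpotCenter:
    def test_solid_square_both_methods_agree(self):
        m = np.zeros((9, 9), bool)
        m[3:6, 3:6] = True
        (g, g_out) = spot_center_from_mask(m, "gravity")
        (t, _) = spot_center_from_mask(m, "thinning")
        assert g == (4.0, 4.0) and not g_out
        assert t == (4.0, 4.0)

    def test_c_shape_gravity_outside_thinning_inside(self):
        m = np.zeros((21, 21), bool)
        rr, cc = np.mgrid[0:21, 0:21]
        d = np.sqrt((rr - 10) ** 2 + (cc - 10) ** 2)
        m[(d >= 6) & (d <= 9)] = True
        m[(cc > 10) & (np.abs(rr - 10) < 4)] = False  # open the ring -> C
        (g, g_out) = spot_center_from_mask(m, "gravity")
        assert g_out
        (t, _) = spot_center_from_mask(m, "thinning")
        assert m[int(round(t[0])), int(round(t[1]))]

    def test_disk_thinning_center_matches_distance_transform(self):
        m = disk_mask((21, 21), (10, 10), 5)
        (t, _) = spot_center_from_mask(m, "thinning")
        edt = ndimage.distance_transform_edt(m)
        best = np.unravel_index(np.argmax(edt), edt.shape)
        assert abs(t[0] - best[0]) <= 1 and abs(t[1] - best[1]) <= 1


class TestSelectSpots:
    @pytest.fixture
    def spots(self):
        imgs = []
        canvas = np.zeros((40, 60), bool)
        canvas[2:12, 2:12] = True        # area 100
        canvas[20:25, 20:28] = True      # area 40
        canvas[30:31, 40:43] = True      # area 3
        return detect_spots(canvas)

    def test_p1_largest_only(self, spots):
        out = select_spots(spots, "P1")
        assert [s.area for s in out] == [100]

    def test_p2_threshold_size(self, spots):
        out = select_spots(spots, "P2", k=2, min_size=5)
        assert [s.area for s in out] == [100, 40]
        out3 = select_spots(spots, "P2", k=3, min_size=5)
        assert [s.area for s in out3] == [100, 40]  # 3 px spot under threshold

    def test_p3_ratio_rule(self, spots):
        out = select_spots(spots, "P3", min_area=1, min_ratio=0.02)
        assert [s.area for s in out] == [100, 40, 3]  # 3/100 >= 0.02
        strict = select_spots(spots, "P3", min_area=1, min_ratio=0.1)
        assert [s.area for s in strict] == [100, 40]

    def test_empty_input(self):
        assert select_spots([], "P1") == []


class TestRegularize:
    def test_annulus_filled_to_disk(self):
        m = disk_mask((25, 25), (12, 12), 8) & ~disk_mask((25, 25), (12, 12), 4)
        (spot,) = detect_spots(m)
        (out,) = regularize_spots([spot], m.shape)
        assert out.mask(m.shape)[12, 12]
        assert out.area >= disk_mask((25, 25), (12, 12), 8).sum() - 8

    def test_two_close_squares_unified(self):
        m = np.zeros((15, 15), bool)
        m[5:8, 3:6] = True
        m[5:8, 7:10] = True  # 1-pixel gap
        spots = detect_spots(m)
        assert len(spots) == 2
        out = regularize_spots(spots, m.shape, smooth_radius=0, merge_distance=2)
        assert len(out) == 1

    def test_protrusion_removed_set_difference_oracle(self):
        disk = disk_mask((30, 30), (15, 12), 6)
        m = disk.copy()
        m[15, 18:24] = True  # 1-px-wide, 6-px-long protrusion
        (spot,) = detect_spots(m)
        out = regularize_spots([spot], m.shape, smooth_radius=2,
                               merge_distance=0)
        result = np.zeros_like(m)
        for s in out:
            result |= s.mask(m.shape)
        assert np.array_equal(result, disk)  # area change == protrusion area

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        blob = ndimage.binary_dilation(rng.random((30, 30)) < 0.08,
                                       disk_se(2).astype(bool))
        blob[:2] = blob[-2:] = False
        blob[:, :2] = blob[:, -2:] = False
        spots = detect_spots(blob)
        if not spots:
            pytest.skip("degenerate random blob")
        once = regularize_spots(spots, blob.shape)
        twice = regularize_spots(once, blob.shape)
        m1 = np.zeros(blob.shape, bool)
        m2 = np.zeros(blob.shape, bool)
        for s in once:
            m1 |= s.mask(blob.shape)
        for s in twice:
            m2 |= s.mask(blob.shape)
        assert np.array_equal(m1, m2)
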