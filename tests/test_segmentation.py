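"""Thresholding, clustering, the SAC merge rule and lesion labelling."""

import numpy as np
import pytest
from scipy import ndimage

from petseg.phantom import Lesion, PhantomSpec, generate
from petseg.segmentation import (
    DegenerateInputError,
    fit_gmm_map,
    kmeans_1d,
    label_lesions,
    sac_coefficient,
    sac_decide,
    segment,
    segment_clustering,
    segment_sac,
    segment_threshold_abs,
    segment_threshold_rel,
)
from petseg.suv_io import AlignmentError, PETVolume

from conftest import make_rois


def lloyd_oracle(values, k):
    """Independent, deliberately naive Lloyd iteration (same percentile init)."""
    v = np.asarray(values, float)
    centers = [np.percentile(v, 100.0 * (2 * i - 1) / (2 * k)) for i in range(1, k + 1)]
    assign = [-1] * len(v)
    for _ in range(300):
        new = []
        for x in v:
            dists = [abs(x - c) for c in centers]
            new.append(dists.index(min(dists)))
        if new == assign:
            break
        assign = new
        for j in range(k):
            member = [x for x, a in zip(v, assign) if a == j]
            if member:
                centers[j] = sum(member) / len(member)
    order = sorted(range(k), key=lambda j: centers[j])
    rank = {j: r for r, j in enumerate(order)}
    return [centers[j] for j in order], [rank[a] for a in assign]


class TestThresholds:
    def test_absolute_keeps_all_above(self, grid_8):
        vol = PETVolume(np.full((8, 8, 8), 3.0), grid_8.spacing)
        rois = make_rois(np.ones((8, 8, 8), bool), grid_8)
        mask = segment_threshold_abs(vol, rois, 2.5)
        assert mask.mask.all()

    def test_absolute_empty_roi_warns_but_keeps_entry(self, grid_8):
        vol = PETVolume(np.full((8, 8, 8), 2.0), grid_8.spacing)
        rois = make_rois(np.ones((8, 8, 8), bool), grid_8)
        mask = segment_threshold_abs(vol, rois, 2.5)
        assert not mask.mask.any()
        assert 1 in mask.per_roi_masks
        assert mask.info["warnings"]

    def test_absolute_matches_bruteforce_count(self, small_volume):
        rois = make_rois(np.ones((8, 8, 8), bool), small_volume.grid)
        mask = segment_threshold_abs(small_volume, rois, 2.5)
        assert mask.mask.sum() == np.count_nonzero(small_volume.values >= 2.5)

    def test_relative_boundary_voxel_is_included(self, grid_8):
        data = np.full((8, 8, 8), 4.1)
        data[4, 4, 4] = 10.0
        vol = PETVolume(data, grid_8.spacing)
        rois = make_rois(np.ones((8, 8, 8), bool), grid_8)
        mask = segment_threshold_rel(vol, rois, 0.41)
        assert mask.mask.all()  # 4.1 == 0.41 * 10 is kept (>= rule)

    def test_relative_uniform_roi_keeps_everything(self, grid_8):
        vol = PETVolume(np.full((8, 8, 8), 6.0), grid_8.spacing)
        rois = make_rois(np.ones((8, 8, 8), bool), grid_8)
        assert segment_threshold_rel(vol, rois).mask.all()

    def test_relative_thresholds_are_per_roi(self, grid_8):
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 10, (8, 8, 8))
        data[:4] = np.minimum(data[:4], 9.0)
        data[0, 0, 0] = 10.0
        data[7, 7, 7] = 20.0
        labels = np.zeros((8, 8, 8), np.int32)
        labels[:4] = 1
        labels[4:] = 2
        vol = PETVolume(data, grid_8.spacing)
        mask = segment_threshold_rel(vol, make_rois(labels, grid_8), 0.41)
        for lab, cut in ((1, 4.1), (2, 8.2)):
            sel = labels == lab
            expected = sel & (data >= cut)
            assert np.array_equal(mask.per_roi_masks[lab], expected)

    def test_nestedness_in_threshold(self, small_volume):
        rois = make_rois(np.ones((8, 8, 8), bool), small_volume.grid)
        lo = segment_threshold_abs(small_volume, rois, 2.0)
        hi = segment_threshold_abs(small_volume, rois, 5.0)
        assert not (hi.mask & ~lo.mask).any()

    def test_misaligned_grids_rejected(self, small_volume):
        other = make_rois(
            np.ones((8, 8, 8), bool),
            type(small_volume.grid)((8, 8, 8), (1.0, 1.0, 1.0), (0, 0, 0)),
        )
        with pytest.raises(AlignmentError):
            segment_threshold_abs(small_volume, other)


class TestKMeans1D:
    def test_separated_point_masses(self):
        model = kmeans_1d([1, 1, 1, 9, 9, 9], 2)
        assert model.means == pytest.approx([1.0, 9.0])
        assert list(model.assignment) == [0, 0, 0, 1, 1, 1]

    def test_all_equal_values_degenerate(self):
        with pytest.raises(DegenerateInputError):
            kmeans_1d([4.0] * 10, 2)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_independent_lloyd_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 10, size=200)
        model = kmeans_1d(v, k)
        means, assign = lloyd_oracle(v, k)
        assert model.means == pytest.approx(means)
        assert list(model.assignment) == assign

    def test_means_strictly_ascending(self):
        rng = np.random.default_rng(1)
        model = kmeans_1d(rng.normal(5, 2, 300).clip(0), 3)
        assert np.all(np.diff(model.means) > 0)


class TestGMM:
    def test_recovers_well_separated_gaussians(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.1, 500).clip(0)
        b = rng.normal(8.0, 0.5, 500)
        model = fit_gmm_map(np.concatenate([a, b]), 2)
        assert model.means[0] == pytest.approx(1.0, abs=0.1)
        assert model.means[1] == pytest.approx(8.0, abs=0.1)
        correct = (model.assignment[:500] == 0).sum() + (model.assignment[500:] == 1).sum()
        assert correct >= 990

    def test_symmetric_mixture_has_balanced_weights(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(2, 0.5, 400), rng.normal(8, 0.5, 400)]).clip(0)
        model = fit_gmm_map(v, 2)
        assert model.weights[0] == pytest.approx(0.5, abs=0.05)

    def test_map_boundary_is_contiguous_on_unimodal_data(self):
        # 2-class MAP rule on a single Gaussian: each class occupies
        # contiguous intensity intervals (posterior monotonicity)
        rng = np.random.default_rng(3)
        v = rng.normal(5, 1, 600).clip(0)
        model = fit_gmm_map(v, 2)
        order = np.argsort(v)
        labels_sorted = model.assignment[order]
        switches = np.count_nonzero(np.diff(labels_sorted))
        assert switches <= 2  # at most two boundaries for k=2 in 1D

    def test_agrees_with_sklearn_em(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(4)
        v = np.concatenate([
            rng.normal(1.5, 0.3, 300), rng.normal(4, 0.8, 300), rng.normal(9, 0.6, 200)
        ]).clip(0)
        mine = fit_gmm_map(v, 3)
        gm = sklearn.GaussianMixture(
            3, init_params="kmeans", random_state=0, tol=1e-7, max_iter=1000
        ).fit(v.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        assert mine.means == pytest.approx(gm.means_.ravel()[order], abs=0.02)
        assert mine.weights == pytest.approx(gm.weights_[order], abs=0.02)

    def test_point_mass_class_survives_variance_floor(self):
        v = np.concatenate([np.full(50, 1.0), np.full(50, 9.0), [5.0]])
        model = fit_gmm_map(v, 2)
        assert model.means[0] == pytest.approx(1.0, abs=0.2)
        assert model.means[1] == pytest.approx(9.0, abs=0.2)

    def test_too_few_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_gmm_map([1.0, 2.0, 3.0], 2)


class TestSACRule:
    def test_coefficient_closed_forms(self):
        def model_with_means(m1, m3):
            assignment = np.array([0, 1, 2])
            return type("M", (), {"k": 3, "means": np.array([m1, (m1 + m3) / 2, m3])})()

        assert sac_coefficient(model_with_means(5.0, 5.0 + 1e-9)) == pytest.approx(0.0, abs=1e-9)
        assert sac_coefficient(model_with_means(0.0, 7.0)) == pytest.approx(1.0)
        assert sac_coefficient(model_with_means(0.6, 19.4)) == pytest.approx(0.94)

    @pytest.mark.parametrize(
        "coef,branch",
        [
            (0.80, "merge_two_lower"),
            (0.94, "merge_two_higher"),
            (0.92, "two_classes"),
            (0.0, "merge_two_lower"),
            (0.90, "two_classes"),
            (1.0, "merge_two_higher"),
        ],
    )
    def test_branch_selection(self, coef, branch):
        assert sac_decide(coef).branch == branch

    def test_branches_partition_the_unit_interval(self):
        seen = {sac_decide(c / 1000).branch for c in range(1001)}
        assert seen == {"merge_two_lower", "two_classes", "merge_two_higher"}

    def test_out_of_range_coefficient_rejected(self):
        with pytest.raises(ValueError):
            sac_decide(1.2)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            sac_decide(0.5, thresholds=(0.95, 0.90))


class TestSegmentSAC:
    def _phantom(self, background, lesion_suv, psf_fwhm=6.0, margin=3):
        spec = PhantomSpec(
            shape=(48, 48, 48),
            spacing=(2.0, 2.0, 2.0),
            background_suv=background,
            lesions=[Lesion((48.0, 48.0, 48.0), (12.0, 12.0, 12.0), lesion_suv)],
            psf_fwhm_mm=psf_fwhm,
            noise_sd=0.05 * max(background, 0.1),
            seed=9,
            roi_margin_voxels=margin,
        )
        return generate(spec)

    def test_high_contrast_includes_border(self):
        # background 0.2 vs lesion 10 with a mild blur and a generous ROI:
        # coef >= 0.94, border joins lesion, so the SAC mask contains the
        # 2-class k-means mask
        vol, _, rois = self._phantom(0.2, 10.0, psf_fwhm=3.0, margin=5)
        sac = segment_sac(vol, rois, "kmeans")
        assert sac.info["per_roi"][1]["branch"] == "merge_two_higher"
        two = segment_clustering(vol, rois, "kmeans", 2)
        assert not (two.mask & ~sac.mask).any()

    def test_low_contrast_excludes_border(self):
        # background 2 vs lesion 4: coef ~ 0.33, border joins background,
        # so the mask is a subset of the border-inclusive alternative
        vol, _, rois = self._phantom(2.0, 4.0)
        sac = segment_sac(vol, rois, "kmeans")
        assert sac.info["per_roi"][1]["branch"] == "merge_two_lower"
        two = segment_clustering(vol, rois, "kmeans", 2)
        assert not (sac.mask & ~two.mask).any()

    def test_uniform_roi_takes_fallback(self, grid_8):
        vol = PETVolume(np.full((8, 8, 8), 3.0), grid_8.spacing)
        rois = make_rois(np.ones((8, 8, 8), bool), grid_8)
        mask = segment_sac(vol, rois, "kmeans")
        assert mask.info["per_roi"][1]["branch"] == "fallback_rel"
        assert mask.info["warnings"]
        assert mask.mask.all()  # uniform ROI: everything >= 41% of max

    def test_repeated_runs_bit_identical(self, blurred_phantom):
        vol, _, rois = blurred_phantom
        a = segment_sac(vol, rois, "bayes")
        b = segment_sac(vol, rois, "bayes")
        assert np.array_equal(a.mask, b.mask)


class TestSegmentClustering:
    def test_kmeans_two_point_roi(self, grid_8):
        data = np.ones((8, 8, 8))
        data[:, :, 4:] = 9.0
        vol = PETVolume(data, grid_8.spacing)
        rois = make_rois(np.ones((8, 8, 8), bool), grid_8)
        mask = segment_clustering(vol, rois, "kmeans", 2)
        assert np.array_equal(mask.mask, data == 9.0)

    def test_bayes_agrees_on_separated_modes(self, grid_8):
        rng = np.random.default_rng(12)
        data = np.where(
            rng.random((8, 8, 8)) > 0.5,
            rng.normal(9, 0.3, (8, 8, 8)),
            rng.normal(1, 0.3, (8, 8, 8)),
        ).clip(0)
        vol = PETVolume(data, grid_8.spacing)
        rois = make_rois(np.ones((8, 8, 8), bool), grid_8)
        km = segment_clustering(vol, rois, "kmeans", 2)
        gm = segment_clustering(vol, rois, "bayes", 2)
        assert np.array_equal(km.mask, gm.mask)

    def test_no_voxel_outside_roi_is_labelled(self, small_volume):
        labels = np.zeros((8, 8, 8), np.int32)
        labels[2:6, 2:6, 2:6] = 1
        rois = make_rois(labels, small_volume.grid)
        for method in ("abs25", "rel41", "kmeans", "bayes", "sac-kmeans", "sac-bayes"):
            mask = segment(small_volume, rois, method)
            assert not (mask.mask & (labels == 0)).any(), method


def flood_fill_oracle(mask, connectivity):
    """Reference connected components by explicit BFS flood fill."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity, order) in {(6, 1)} or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.add(p)
            for off in offsets:
                q = tuple(np.add(p, off))
                if all(0 <= qi < si for qi, si in zip(q, mask.shape)) \
                        and mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


class TestLabelLesions:
    def test_two_separated_cubes(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[1:4, 1:4, 1:4] = True
        mask[6:9, 6:9, 6:9] = True
        lesions = label_lesions(mask)
        assert lesions.n_lesions == 2

    def test_corner_touch_is_one_component_under_26(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True
        assert label_lesions(mask, 26).n_lesions == 1
        assert label_lesions(mask, 6).n_lesions == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(17)
        mask = rng.random((12, 12, 12)) > 0.7
        lesions = label_lesions(mask, connectivity)
        oracle = flood_fill_oracle(mask, connectivity)
        assert lesions.n_lesions == len(oracle)
        mine = {
            frozenset((int(a), int(b), int(c)) for a, b, c in zip(*idx))
            for idx in lesions.components.values()
        }
        theirs = {
            frozenset((int(a), int(b), int(c)) for a, b, c in comp)
            for comp in oracle
        }
        assert mine == theirs

    def test_labels_ordered_by_descending_size(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[0:2, 0:2, 0:2] = True      # 8 voxels
        mask[8:12, 8:12, 8:12] = True   # 64 voxels
        lesions = label_lesions(mask)
        sizes = [len(lesions.components[j][0]) for j in sorted(lesions.components)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_mask_gives_empty_set(self):
        lesions = label_lesions(np.zeros((5, 5, 5), bool))
        assert lesions.n_lesions == 0
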