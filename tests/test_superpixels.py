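import numpy as np
import pytest

from gliotype.bayes import PosteriorMap
from gliotype.classes import N_CLASSES, class_index
from gliotype.io_volumes import MultimodalVolume
from gliotype.superpixels import (
    LesionSegmentation,
    SuperpixelMap,
    average_probabilities,
    compute_superpixels,
    extract_lesion,
    highgrade_volume,
    render_colour_map,
)


def _sp_volume(array3, extra=None):
    """Wrap one 2D/3D pattern as the (PDn, FLAIR, p) channel set."""
    arr = np.asarray(array3, dtype=float)
    chans = {"PDn": arr, "FLAIR": arr if extra is None else extra, "p": np.abs(arr)}
    return MultimodalVolume(chans, voxel_size=(1.0, 1.0, 5.0))


class TestComputeSuperpixels:
    def test_uniform_slice_count_matches_grid_arithmetic(self):
        """A uniform 256² slice upsampled ×4 to 1024² yields ≈ (1024/30)² regions."""
        vol = _sp_volume(np.full((256, 256, 1), 0.5))
        labels = compute_superpixels(vol, np.ones((256, 256, 1), bool),
                                     grid_size=30, upsample_factor=4)
        n = len(np.unique(labels[labels > 0]))
        expected = int(np.ceil(1024 / 30)) ** 2
        assert abs(n - expected) / expected < 0.25

    def test_identical_slices_identical_geometry(self, rng):
        sl = rng.random((64, 64))
        vol = _sp_volume(np.stack([sl, sl], axis=2))
        labels = compute_superpixels(vol, np.ones((64, 64, 2), bool),
                                     grid_size=20, upsample_factor=2)
        a, b = labels[:, :, 0], labels[:, :, 1]
        # same geometry, ids offset by the slice-0 count
        assert np.array_equal(a > 0, b > 0)
        offset = b[a > 0] - a[a > 0]
        assert np.all(offset == offset[0])

    def test_high_contrast_disc_boundary_respected(self):
        """Superpixels do not leak across a strong boundary farther than the
        SLIC spatial step."""
        n, f, grid = 128, 4, 30
        yy, xx = np.mgrid[:n, :n]
        disc = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 < (n // 3) ** 2
        img = np.where(disc, 0.85, 0.15)[..., None]
        vol = _sp_volume(img)
        labels = compute_superpixels(vol, np.ones((n, n, 1), bool),
                                     grid_size=grid, upsample_factor=f)
        step_native = grid / f
        disc3 = disc[..., None]
        for sp in np.unique(labels[labels > 0]):
            m = labels == sp
            n_in, n_out = int((m & disc3).sum()), int((m & ~disc3).sum())
            if n_in and n_out:
                # minor side must be a thin sliver along the boundary
                minor = min(n_in, n_out)
                assert minor <= step_native ** 2 * 4

    def test_every_in_mask_voxel_has_one_id(self, small_phantom):
        volume, truth = small_phantom["volume"], small_phantom["truth"]
        mask = truth.labels > 0
        labels = compute_superpixels(volume, mask, upsample_factor=2)
        assert np.all(labels[mask] > 0)
        assert np.all(labels[~mask] == 0)

    def test_empty_mask_slice_has_no_labels(self):
        vol = _sp_volume(np.full((32, 32, 2), 0.4))
        mask = np.zeros((32, 32, 2), bool)
        mask[:, :, 0] = True
        labels = compute_superpixels(vol, mask, grid_size=10, upsample_factor=1)
        assert np.all(labels[:, :, 1] == 0)
        assert np.all(labels[:, :, 0] > 0)


def _posterior_from(probs):
    probs = np.asarray(probs, dtype=np.float32)
    return PosteriorMap(probs=probs, out_of_support=np.zeros(probs.shape[:3], bool))


class TestAverageProbabilities:
    def test_constant_field(self):
        vec = np.array([0.1, 0.2, 0.3, 0.1, 0.1, 0.1, 0.1], dtype=np.float32)
        probs = np.broadcast_to(vec, (4, 4, 1, 7)).copy()
        labels = np.repeat(np.arange(1, 5), 4).reshape(4, 4, 1)
        sp = average_probabilities(_posterior_from(probs), labels)
        for v in sp.sp_probs.values():
            np.testing.assert_allclose(v, vec, rtol=1e-6)

    def test_two_voxel_average(self):
        probs = np.zeros((2, 1, 1, 7))
        probs[0, 0, 0, 0] = 1.0
        probs[1, 0, 0, 1] = 1.0
        labels = np.ones((2, 1, 1), dtype=np.int32)
        sp = average_probabilities(_posterior_from(probs), labels)
        np.testing.assert_allclose(sp.sp_probs[1][:2], [0.5, 0.5], rtol=1e-6)

    def test_bruteforce_means_and_mass_conservation(self, rng):
        probs = rng.dirichlet(np.ones(7), size=(8, 8, 2)).astype(np.float32)
        labels = rng.integers(1, 9, size=(8, 8, 2)).astype(np.int32)
        sp = average_probabilities(_posterior_from(probs), labels)
        for sp_id in np.unique(labels):
            m = labels == sp_id
            np.testing.assert_allclose(sp.sp_means[sp_id], probs[m].mean(axis=0), atol=1e-6)
            assert sp.sp_size[sp_id] == int(m.sum())
            assert sp.sp_probs[sp_id].sum() == pytest.approx(1.0, abs=1e-6)
        # Σ_id size·mean == Σ_voxels posterior, class by class
        total = sum(sp.sp_size[i] * sp.sp_means[i] for i in sp.sp_means)
        np.testing.assert_allclose(total, probs.reshape(-1, 7).sum(axis=0), rtol=1e-5)


def _manual_spmap(shape, assignments):
    """assignments: dict id -> (mask, prob_vector)."""
    labels = np.zeros(shape, dtype=np.int32)
    sp_probs, sp_size = {}, {}
    for sp_id, (m, vec) in assignments.items():
        labels[m] = sp_id
        sp_probs[sp_id] = np.asarray(vec, dtype=float)
        sp_size[sp_id] = int(np.count_nonzero(m))
    return SuperpixelMap(labels, sp_probs, sp_size)


ABN = np.zeros(7)
ABN[class_index("GII")] = 0.9
ABN[class_index("GM")] = 0.1
NORM = np.zeros(7)
NORM[class_index("GM")] = 1.0


class TestExtractLesion:
    def test_all_normal_is_empty(self):
        m = np.zeros((4, 4, 2), bool)
        m[:2] = True
        sp = _manual_spmap((4, 4, 2), {1: (m, NORM), 2: (~m, NORM)})
        lesion = extract_lesion(sp, (1, 1, 1))
        assert not lesion.lesion_mask.any()
        assert lesion.lesion_volume_ml == 0.0

    def test_largest_component_retained(self):
        shape = (30, 10, 1)
        assignments = {}
        # blob A: ids 1..9 abnormal, connected, 9 superpixels
        for k in range(9):
            m = np.zeros(shape, bool)
            m[2 * k: 2 * k + 2, :5] = True
            assignments[k + 1] = (m, ABN)
        # blob B: one distant abnormal superpixel
        mb = np.zeros(shape, bool)
        mb[25:28, 7:] = True
        assignments[10] = (mb, ABN)
        # background normal
        used = np.zeros(shape, bool)
        for m, _ in assignments.values():
            used |= m
        assignments[11] = (~used, NORM)
        sp = _manual_spmap(shape, assignments)
        lesion = extract_lesion(sp, (1, 1, 1))
        assert lesion.component_count_considered == 2
        assert lesion.superpixel_ids == frozenset(range(1, 10))
        assert not lesion.lesion_mask[25:28, 7:].any()

    def test_invariant_to_id_relabelling(self):
        shape = (8, 8, 1)
        m = np.zeros(shape, bool)
        m[:4] = True
        sp1 = _manual_spmap(shape, {1: (m, ABN), 2: (~m, NORM)})
        sp2 = _manual_spmap(shape, {17: (m, ABN), 5: (~m, NORM)})
        l1 = extract_lesion(sp1, (2, 2, 2))
        l2 = extract_lesion(sp2, (2, 2, 2))
        np.testing.assert_array_equal(l1.lesion_mask, l2.lesion_mask)
        assert l1.lesion_volume_ml == l2.lesion_volume_ml

    def test_threshold_is_strict(self):
        half = np.zeros(7)
        half[class_index("VO")] = 0.5
        half[class_index("GM")] = 0.5
        m = np.ones((4, 4, 1), bool)
        sp = _manual_spmap((4, 4, 1), {1: (m, half)})
        assert not extract_lesion(sp, (1, 1, 1)).lesion_mask.any()


class TestColourMap:
    def _one_sp(self, vec):
        m = np.ones((2, 2, 1), bool)
        sp = _manual_spmap((2, 2, 1), {1: (m, np.asarray(vec, float))})
        lesion = LesionSegmentation(m, 1, 4e-3, frozenset([1]))
        return render_colour_map(sp, lesion).rgb[0, 0, 0]

    def _vec(self, **probs):
        v = np.zeros(7)
        for name, p in probs.items():
            v[class_index(name)] = p
        return v

    def test_pure_giv_is_red(self):
        np.testing.assert_allclose(self._one_sp(self._vec(GIV=1.0)), [1, 0, 0], atol=1e-6)

    def test_pure_oedema_is_black(self):
        np.testing.assert_allclose(self._one_sp(self._vec(VO=1.0)), [0, 0, 0], atol=1e-6)

    def test_equal_gii_giv_is_yellow(self):
        rgb = self._one_sp(self._vec(GII=0.5, GIV=0.5))
        np.testing.assert_allclose(rgb, [1 / np.sqrt(2), 1 / np.sqrt(2), 0], atol=1e-6)

    def test_outside_lesion_is_black(self):
        m = np.zeros((4, 4, 1), bool)
        m[:2] = True
        sp = _manual_spmap((4, 4, 1), {1: (m, self._vec(GIV=1.0)), 2: (~m, NORM)})
        lesion = LesionSegmentation(m, 1, 1.0, frozenset([1]))
        rgb = render_colour_map(sp, lesion).rgb
        assert np.all(rgb[~m] == 0)

    def test_norm_bounded_by_tumour_probability(self, rng):
        for _ in range(100):
            v = rng.dirichlet(np.ones(7))
            rgb = self._one_sp(v)
            tum = v[[class_index(n) for n in ("GII", "GIV", "Ne")]].sum()
            assert np.linalg.norm(rgb) <= tum + 1e-6


class TestHighGradeVolume:
    def test_no_giv_gives_zero(self):
        m = np.ones((4, 4, 1), bool)
        sp = _manual_spmap((4, 4, 1), {1: (m, ABN)})
        lesion = LesionSegmentation(m, 1, 16e-3, frozenset([1]))
        assert highgrade_volume(sp, lesion, (1, 1, 1)) == 0.0

    def test_single_superpixel_volume(self):
        vec = np.zeros(7)
        vec[class_index("GIV")] = 0.6
        vec[class_index("GM")] = 0.4
        m = np.ones((10, 10, 10), bool)  # 1000 voxels × 1 mm³ = 1 ml
        sp = _manual_spmap((10, 10, 10), {1: (m, vec)})
        lesion = LesionSegmentation(m, 1, 1.0, frozenset([1]))
        assert highgrade_volume(sp, lesion, (1, 1, 1)) == pytest.approx(1.0)
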