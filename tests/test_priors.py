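import numpy as np
import pandas as pd
import pytest

from gliotype.classes import CLASS_BY_NAME, CLASSES
from gliotype.io_volumes import LabelVolume
from gliotype.mrsi import MRSIGeometry
from gliotype.priors import (
    BinGrid4D,
    ROIRuleSet,
    build_pdd,
    derive_tumour_rois,
    fit_bin_grid,
    lookup_density,
    split_necrosis,
)

GII = CLASS_BY_NAME["GII"]
GIV = CLASS_BY_NAME["GIV"]
NE = CLASS_BY_NAME["Ne"]


def _table(fracs):
    rows = []
    for (i, j), (fn, f2, f4) in fracs.items():
        rows.append({"i": i, "j": j, "fraction_normal": fn,
                     "fraction_GII": f2, "fraction_GIV": f4})
    return pd.DataFrame(rows)


class TestTumourROIs:
    geometry = MRSIGeometry(origin=(0, 0), block_size=(2, 2), z_start=0,
                            n_slices=1, grid_shape=(3, 3))
    shape = (6, 6, 1)

    def test_purity_rule(self):
        table = _table({(0, 0): (0.05, 0.92, 0.03), (0, 1): (0.2, 0.0, 0.8),
                        **{(i, j): (1.0, 0.0, 0.0) for i in range(3) for j in range(3)
                           if (i, j) not in ((0, 0), (0, 1))}})
        lv = derive_tumour_rois(table, self.geometry, ROIRuleSet(), "GII", self.shape)
        # only the 0.92-pure voxel labels its 2×2×1 block
        assert lv.counts()["GII"] == 4
        assert np.all(lv.labels[0:2, 0:2, 0] == GII.index)
        assert np.all(lv.labels[0:2, 2:4, 0] == 0)

    def test_nine_voxel_enumeration(self):
        """Label count over a 9-voxel MRSI grid equals the hand count."""
        fr = {(0, 0): (0.0, 0.95, 0.05), (0, 1): (0.0, 0.91, 0.09),
              (0, 2): (0.1, 0.90, 0.00),   # exactly 0.90 is NOT > 0.90
              (1, 0): (0.0, 0.05, 0.95), (1, 1): (0.5, 0.5, 0.0),
              (1, 2): (0.0, 1.0, 0.0), (2, 0): (1.0, 0.0, 0.0),
              (2, 1): (0.05, 0.92, 0.03), (2, 2): (0.2, 0.8, 0.0)}
        lv = derive_tumour_rois(_table(fr), self.geometry, ROIRuleSet(), "GII", self.shape)
        # pure-GII voxels by hand: (0,0), (0,1), (1,2), (2,1) -> 4 blocks of 4
        assert lv.counts()["GII"] == 16

    def test_giv_patient_uses_giv_fraction(self):
        table = _table({(i, j): (0.05, 0.0, 0.95) if (i, j) == (1, 1) else (1.0, 0.0, 0.0)
                        for i in range(3) for j in range(3)})
        lv = derive_tumour_rois(table, self.geometry, ROIRuleSet(), "GIV", self.shape)
        assert lv.counts()["GIV"] == 4

    def test_out_of_bounds_geometry_rejected(self):
        table = _table({(i, j): (1.0, 0.0, 0.0) for i in range(3) for j in range(3)})
        with pytest.raises(ValueError, match="exceeds"):
            derive_tumour_rois(table, self.geometry, ROIRuleSet(), "GII", (5, 6, 1))


class TestNecrosisSplit:
    def _giv_roi(self, n):
        labels = np.zeros((n, 1, 1), dtype=np.int32)
        labels[:, 0, 0] = GIV.index
        return LabelVolume(labels, {GIV.index: GIV})

    def test_threshold_relabels(self):
        roi = self._giv_roi(2)
        p = np.array([5e-3, 1e-3]).reshape(2, 1, 1)
        out = split_necrosis(roi, p)
        assert out.labels[0, 0, 0] == NE.index   # p above 4e-3 mm²/s
        assert out.labels[1, 0, 0] == GIV.index

    def test_counting(self, rng):
        roi = self._giv_roi(100)
        p = np.full((100, 1, 1), 1e-3)
        hot = rng.choice(100, size=30, replace=False)
        p[hot] = 6e-3
        out = split_necrosis(roi, p)
        assert out.counts() == {"GIV": 70, "Ne": 30}

    def test_rejects_mixed_roi(self):
        labels = np.full((2, 1, 1), GII.index, dtype=np.int32)
        with pytest.raises(ValueError, match="GIV-only"):
            split_necrosis(LabelVolume(labels, {GII.index: GII}), np.zeros((2, 1, 1)))


class TestBinGrid:
    def test_uniform_percentile_edges(self, rng):
        samples = {GII: rng.uniform(0, 1, size=(200_000, 4))}
        grid = fit_bin_grid(samples, bins=50)
        for k in range(4):
            assert grid.edges[k][0] == pytest.approx(0.005, abs=0.002)
            assert grid.edges[k][-1] == pytest.approx(0.995, abs=0.002)
            np.testing.assert_allclose(np.diff(grid.edges[k]),
                                       np.diff(grid.edges[k])[0], rtol=1e-9)

    def test_pooling_invariance(self, rng):
        pool = rng.normal(size=(1000, 4))
        single = fit_bin_grid({GII: pool}, bins=20)
        split = fit_bin_grid({GII: pool[:400], GIV: pool[400:]}, bins=20)
        for k in range(4):
            np.testing.assert_allclose(single.edges[k], split.edges[k], rtol=1e-12)

    def test_two_bin_hand_computation(self):
        vals = np.arange(11.0)
        samples = {GII: np.stack([vals] * 4, axis=1)}
        grid = fit_bin_grid(samples, bins=2)
        lo, hi = np.percentile(vals, (0.5, 99.5))
        for k in range(4):
            assert len(grid.edges[k]) == 3
            assert grid.edges[k][1] == pytest.approx((lo + hi) / 2)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            fit_bin_grid({}, bins=10)


@pytest.fixture(scope="module")
def unit_grid():
    edges = tuple(np.linspace(0.0, 1.0, 11) for _ in range(4))
    return BinGrid4D(edges, bins=10)


class TestPDD:
    def test_single_sample(self, unit_grid):
        pdd = build_pdd(np.array([[0.55, 0.15, 0.35, 0.75]]), unit_grid, GII)
        nz = np.nonzero(pdd.density)
        assert len(nz[0]) == 1
        assert tuple(a[0] for a in nz) == (5, 1, 3, 7)
        assert pdd.density[nz][0] == pytest.approx(1.0 / unit_grid.bin_volume)

    def test_unit_integral(self, unit_grid, rng):
        pdd = build_pdd(rng.random((5_000, 4)), unit_grid, GII)
        assert pdd.integral == pytest.approx(1.0, abs=1e-9)

    def test_hand_counts_proportional(self, unit_grid):
        # 3 samples in bin A, 2 in bin B, 1 in bin C
        a, b, c = [0.05] * 4, [0.55] * 4, [0.95] * 4
        pdd = build_pdd(np.array([a, a, a, b, b, c]), unit_grid, GII)
        dens = sorted(pdd.density[pdd.density > 0], reverse=True)
        np.testing.assert_allclose(np.array(dens) / dens[-1], [3, 2, 1], rtol=1e-12)

    def test_clipping_equivalence(self, unit_grid):
        """A sample beyond the grid is binned exactly like one moved to the
        nearest edge-bin centre."""
        outside = np.array([[1.7, -0.3, 0.5, 2.0]])
        at_edge = np.array([[0.95, 0.05, 0.5, 0.95]])
        p1 = build_pdd(outside, unit_grid, GII)
        p2 = build_pdd(at_edge, unit_grid, GII)
        np.testing.assert_array_equal(p1.density, p2.density)

    def test_no_samples_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            build_pdd(np.empty((0, 4)), unit_grid, GII)

    def test_gaussian_convergence(self, unit_grid):
        """Mean absolute bin error against the analytic density shrinks with n."""
        from scipy.stats import norm

        mu, sd = 0.5, 0.12
        centers = 0.5 * (unit_grid.edges[0][:-1] + unit_grid.edges[0][1:])
        width = np.diff(unit_grid.edges[0])[0]
        marg = norm.pdf(centers, mu, sd)
        analytic = (marg[:, None, None, None] * marg[None, :, None, None]
                    * marg[None, None, :, None] * marg[None, None, None, :])
        errs = {}
        for n in (1_000, 100_000):
            x = np.random.default_rng(5).normal(mu, sd, size=(n, 4))
            pdd = build_pdd(x, unit_grid, GII)
            errs[n] = float(np.abs(pdd.density - analytic).mean())
        assert errs[100_000] < errs[1_000]


class TestLookup:
    def test_point_lookups(self, unit_grid):
        pdd = build_pdd(np.array([[0.55, 0.15, 0.35, 0.75]]), unit_grid, GII)
        assert lookup_density(pdd, np.array([0.57, 0.11, 0.31, 0.79])) == pytest.approx(
            1.0 / unit_grid.bin_volume
        )
        assert lookup_density(pdd, np.array([0.05, 0.05, 0.05, 0.05])) == 0.0

    def test_bruteforce_indexing(self, unit_grid, rng):
        """Vectorised lookup equals per-point manual bin indexing at 1000 points."""
        pdd = build_pdd(rng.random((2_000, 4)), unit_grid, GII)
        xs = rng.uniform(-0.2, 1.2, size=(1_000, 4))
        got = lookup_density(pdd, xs)
        for m in range(0, 1_000, 7):  # spot-check a third of them point-by-point
            idx = []
            for k in range(4):
                e = unit_grid.edges[k]
                i = int(np.searchsorted(e, xs[m, k], side="right")) - 1
                idx.append(min(max(i, 0), unit_grid.bins - 1))
            assert got[m] == pdd.density[tuple(idx)]


def test_all_class_pdds_unit_integral(trained_pdds):
    for cls in CLASSES:
        pdd = trained_pdds[cls]
        assert np.all(pdd.density >= 0)
        assert pdd.integral == pytest.approx(1.0, abs=1e-9)


def test_roi_ruleset_validation():
    with pytest.raises(ValueError):
        ROIRuleSet(mrsi_purity_threshold=0.0)
    with pytest.raises(ValueError):
        ROIRuleSet(necrosis_p_threshold=-1.0)
    assert ROIRuleSet().necrosis_p_threshold == pytest.approx(4e-3)
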