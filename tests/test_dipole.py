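"""Linear-dipole pair correlation: oracles, nulls, aggregation, peak stats."""

import numpy as np
import pytest

from clasifish import (
    DipoleCurve,
    DipoleSettings,
    aggregate,
    dipole_correlation,
    exclude_noise,
    peak_stats,
)


def settings(**kw):
    base = dict(
        max_distance_um=8.0, step_um=1.0, n_dipoles_per_bin=20000,
        min_object_area_um2=0.0, seed=0,
    )
    base.update(kw)
    return DipoleSettings(**base)


def naive_curve(a, b, st, pixel=1.0):
    """O(N^2) ordered pixel-pair counter, the brute-force reference."""
    H, W = a.shape
    ys, xs = np.mgrid[0:H, 0:W]
    pts = np.column_stack([ys.ravel(), xs.ravel()])
    av, bv = a.ravel(), b.ravel()
    centers = st.bin_centers_um()
    edges = np.concatenate([[centers[0] - st.step_um / 2], centers + st.step_um / 2])
    hits = np.zeros(len(centers))
    tot = np.zeros(len(centers))
    for i in range(len(pts)):
        d = np.hypot(pts[:, 0] - pts[i, 0], pts[:, 1] - pts[i, 1]) * pixel
        bi = np.digitize(d, edges) - 1
        ok = (bi >= 0) & (bi < len(centers))
        np.add.at(tot, bi[ok], 1)
        if av[i]:
            np.add.at(hits, bi[ok], bv[ok])
    return (hits / tot) / (a.mean() * b.mean()), tot


class TestDipoleCorrelation:
    def test_all_foreground_is_unity(self):
        ones = np.ones((64, 64), bool)
        cur = dipole_correlation(ones, ones, settings())
        assert np.allclose(cur.g[np.isfinite(cur.g)], 1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dipole_correlation(
                np.zeros((16, 16), bool), np.ones((16, 16), bool), settings()
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dipole_correlation(
                np.ones((16, 16), bool), np.ones((8, 8), bool), settings()
            )

    def test_exhaustive_equals_naive_oracle(self, rng):
        a = rng.random((48, 48)) < 0.08
        b = rng.random((48, 48)) < 0.12
        st = settings(n_dipoles_per_bin="exhaustive")
        cur = dipole_correlation(a, b, st)
        g_ref, tot_ref = naive_curve(a, b, st)
        assert np.array_equal(cur.n_dipoles, tot_ref.astype(np.int64))
        assert np.allclose(cur.g, g_ref, equal_nan=True)

    def test_square_autocorrelation_vs_oracle(self, rng):
        mask = np.zeros((100, 100), bool)
        mask[45:55, 45:55] = True
        st = settings(max_distance_um=12.0, n_dipoles_per_bin="exhaustive")
        cur = dipole_correlation(mask, mask, st)
        g_ref, _ = naive_curve(mask, mask, st)
        assert np.allclose(cur.g, g_ref, equal_nan=True)

    def test_mc_agrees_with_exhaustive_within_3se(self, rng):
        a = rng.random((48, 48)) < 0.10
        b = rng.random((48, 48)) < 0.10
        ref = dipole_correlation(a, b, settings(n_dipoles_per_bin="exhaustive"))
        mc = dipole_correlation(a, b, settings(n_dipoles_per_bin=100000, seed=3))
        ok = np.isfinite(mc.g) & np.isfinite(ref.g)
        z = np.abs(mc.g[ok] - ref.g[ok]) / mc.g_se[ok]
        assert np.max(z) <= 3.0

    def test_exchange_symmetry_exhaustive_exact(self, rng):
        a = rng.random((40, 40)) < 0.1
        b = rng.random((40, 40)) < 0.1
        st = settings(n_dipoles_per_bin="exhaustive")
        gab = dipole_correlation(a, b, st).g
        gba = dipole_correlation(b, a, st).g
        assert np.allclose(gab, gba, equal_nan=True)

    def test_independent_csr_masks_near_unity(self, rng):
        a = rng.random((128, 128)) < 0.2
        b = rng.random((128, 128)) < 0.2
        cur = dipole_correlation(a, b, settings(n_dipoles_per_bin=50000))
        ok = np.isfinite(cur.g)
        assert np.nanmean(np.abs(cur.g[ok] - 1.0)) < 0.05

    def test_deterministic_given_seed(self, rng):
        a = rng.random((48, 48)) < 0.1
        c1 = dipole_correlation(a, a, settings(seed=9))
        c2 = dipole_correlation(a, a, settings(seed=9))
        assert np.array_equal(c1.g, c2.g, equal_nan=True)

    def test_same_object_exclusion_single_object_scores_zero(self):
        """With a single connected object, inter-object autocorrelation has
        no hits at any distance."""
        mask = np.zeros((64, 64), bool)
        mask[28:36, 28:36] = True
        st = settings(exclude_same_object=True, n_dipoles_per_bin="exhaustive")
        cur = dipole_correlation(mask, mask, st)
        assert np.nansum(cur.g) == 0.0
        mc = dipole_correlation(
            mask, mask, settings(exclude_same_object=True, seed=1)
        )
        assert np.nansum(mc.g) == 0.0

    def test_same_object_exclusion_mc_matches_exhaustive(self, rng):
        mask = rng.random((48, 48)) < 0.1
        st_ex = settings(exclude_same_object=True, n_dipoles_per_bin="exhaustive")
        st_mc = settings(exclude_same_object=True, n_dipoles_per_bin=100000, seed=2)
        ref = dipole_correlation(mask, mask, st_ex)
        mc = dipole_correlation(mask, mask, st_mc)
        # sub-pixel-scale bins differ by construction: continuous dipoles of
        # length ~1 px can land both endpoints in one pixel (same object),
        # which pixel-pair enumeration cannot represent; compare r >= 2 px
        ok = (
            np.isfinite(mc.g) & np.isfinite(ref.g) & (mc.g_se > 0)
            & (ref.distance_um >= 2.0)
        )
        z = np.abs(mc.g[ok] - ref.g[ok]) / mc.g_se[ok]
        assert np.max(z) <= 4.0  # a few hundred comparisons


class TestExcludeNoise:
    def test_disjoint_masks_unchanged(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[2:8, 2:8] = True
        b[12:18, 12:18] = True
        st = settings(min_object_area_um2=0.0, exclude_overlap=True)
        oa, ob = exclude_noise(a, b, st, pixel_size_um=1.0)
        assert np.array_equal(oa, a) and np.array_equal(ob, b)

    def test_identical_masks_fully_removed(self):
        a = np.zeros((20, 20), bool)
        a[5:10, 5:10] = True
        st = settings(exclude_overlap=True)
        # overlap exclusion applies between *different* populations only;
        # pass distinct but equal arrays
        oa, ob = exclude_noise(a, a.copy(), st, 1.0)
        assert np.array_equal(oa, a)  # same mask => autocorrelation, kept
        b = a.copy()
        b[5, 5] = False  # no longer identical: cross-taxon overlap removed
        oa, ob = exclude_noise(a, b, st, 1.0)
        assert not (oa & ob).any()

    def test_small_object_removed(self):
        a = np.zeros((30, 30), bool)
        a[0, 0:2] = True  # 2 px at 0.1038 um/px = 0.0215 um^2 < 0.1
        a[10:20, 10:20] = True
        st = settings(min_object_area_um2=0.1)
        oa, _ = exclude_noise(a, a.copy(), st, pixel_size_um=212.55 / 2048)
        assert not oa[0, 0]
        assert oa[15, 15]


class TestAggregate:
    def _flat(self, value, n=10):
        d = np.arange(1, n + 1) * 0.15
        return DipoleCurve(d, np.full(n, float(value)), np.full(n, 100),
                           np.zeros(n), 0.1, 0.1)

    def test_constant_curves_zero_width_ci(self):
        ens = aggregate({"a": [self._flat(1)], "b": [self._flat(1)]})
        assert np.allclose(ens.mean, 1.0)
        assert np.allclose(ens.ci_low, 1.0)
        assert np.allclose(ens.ci_high, 1.0)

    def test_two_groups_mean(self):
        ens = aggregate({"a": [self._flat(0.5)], "b": [self._flat(1.5)]})
        assert np.allclose(ens.mean, 1.0)

    def test_within_group_averaging_first(self):
        ens = aggregate(
            {"a": [self._flat(0.0), self._flat(1.0)], "b": [self._flat(1.5)]}
        )
        assert np.allclose(ens.mean, (0.5 + 1.5) / 2)

    def test_single_group_warns_no_ci(self):
        with pytest.warns(UserWarning, match="single group"):
            ens = aggregate({"a": [self._flat(1)]})
        assert ens.ci_low is None

    def test_ci_covers_truth_for_simulated_groups(self, rng):
        """Bootstrap 95% CI covers the true flat curve in most bins."""
        n_bins = 20
        d = np.arange(1, n_bins + 1) * 0.15
        cover = []
        for rep in range(20):
            groups = {}
            for k in range(8):
                g = 1.0 + rng.normal(0, 0.2, n_bins)
                groups[f"g{k}"] = [
                    DipoleCurve(d, g, np.full(n_bins, 100), np.zeros(n_bins), 0.1, 0.1)
                ]
            ens = aggregate(groups, seed=rep)
            cover.append(np.mean((ens.ci_low <= 1.0) & (1.0 <= ens.ci_high)))
        assert np.mean(cover) >= 0.80


class TestPeakStats:
    def test_triangular_curve(self):
        d = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        g = np.array([1.0, 2.0, 3.0, 2.6667, 2.0, 1.0])
        ps = peak_stats(DipoleCurve(d, g, np.ones(6), np.zeros(6), 0.1, 0.1))
        assert ps.defined
        assert ps.peak_distance_um == 1.5
        # half height 2.0 crossed exactly at 1.0 and 2.5
        assert ps.fwhm_um == pytest.approx(1.5)

    def test_flat_curve_flagged_undefined(self):
        d = np.arange(1, 6) * 0.15
        ps = peak_stats(DipoleCurve(d, np.ones(5), np.ones(5), np.zeros(5), 0.1, 0.1))
        assert not ps.defined

    def test_tie_takes_smallest_distance(self):
        d = np.array([1.0, 2.0, 3.0])
        g = np.array([2.0, 2.0, 1.0])
        ps = peak_stats(DipoleCurve(d, g, np.ones(3), np.zeros(3), 0.1, 0.1))
        assert ps.peak_distance_um == 1.0
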