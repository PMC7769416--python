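import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

import scatterrisk as sr
from scatterrisk.compare import (
    GammaCriteria,
    compare_distributions,
    gamma_index,
    mean_dose_delta,
    passing_rate,
)

from conftest import make_dose_grid


def brute_force_gamma(ref, ev, criteria):
    """Independent gamma oracle: exhaustive offset search with fine step.

    Written directly from the definition; separate interpolation machinery
    (RegularGridInterpolator) and an explicit triple loop over reference
    voxels.  Only usable on tiny grids.
    """
    dta = criteria.distance_mm
    radius = criteria.search_radius_factor * dta
    step = dta / 10.0
    axes = [ev.axis_coords(a) for a in range(3)]
    interp = RegularGridInterpolator(
        axes, ev.values.astype(float), bounds_error=False, fill_value=np.nan
    )
    n = int(round(radius / step))
    offs = np.arange(-n, n + 1) * step  # exact zero at the lattice center
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    d2 = (offsets**2).sum(axis=1)
    offsets = offsets[d2 <= radius**2 + 1e-9]
    d2 = d2[d2 <= radius**2 + 1e-9] / dta**2

    out = np.full(ref.shape, np.nan)
    thresh = criteria.low_dose_threshold_pct / 100.0 * ref.values.max()
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            for k in range(ref.shape[2]):
                r = ref.values[i, j, k]
                if r <= thresh:
                    continue
                center = np.array(
                    [ref.axis_coords(0)[i], ref.axis_coords(1)[j],
                     ref.axis_coords(2)[k]]
                )
                sampled = interp(center + offsets)
                dose_term = ((sampled - r) / (criteria.dose_pct / 100.0 * r)) ** 2
                out[i, j, k] = np.sqrt(np.nanmin(dose_term + d2))
    return out


class TestDelta:
    @pytest.mark.parametrize(
        "mc,tps,expected",
        [
            (52.100, 51.666, -0.833),
            (51.275, 51.579, 0.593),
            (51.258, 51.462, 0.398),
            (51.101, 51.589, 0.955),
        ],
    )
    def test_published_mean_dose_pairs(self, mc, tps, expected):
        assert mean_dose_delta(mc, tps) == pytest.approx(expected, abs=0.002)

    def test_equal_means_and_antisymmetry(self):
        assert mean_dose_delta(10.0, 10.0) == 0.0
        a = mean_dose_delta(10.0, 10.1)
        b = mean_dose_delta(10.1, 10.0)
        # antisymmetric to first order in the difference
        assert a == pytest.approx(-b, abs=0.02)

    def test_printed_formula_flag_flips_normalization(self):
        assert mean_dose_delta(52.100, 51.666, printed_formula=True) == pytest.approx(
            (52.100 - 51.666) / 51.666 * 100.0
        )

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mean_dose_delta(0.0, 1.0)


def smooth_random_grid(rng, shape=(10, 10, 4), spacing=(3.0, 3.0, 3.0)):
    from scipy.ndimage import gaussian_filter

    vals = gaussian_filter(rng.random(shape), sigma=1.5)
    vals = 1.0 + 10.0 * vals
    return sr.VoxelGrid(values=vals, spacing=spacing, units="Gy")


class TestGamma:
    def test_identical_grids_pass_everywhere(self, rng):
        g = smooth_random_grid(rng)
        gamma = gamma_index(g, g)
        assert np.nanmax(gamma) == pytest.approx(0.0, abs=1e-12)
        assert passing_rate(gamma) == 100.0

    def test_uniform_three_percent_offset_is_boundary_pass(self, rng):
        g = smooth_random_grid(rng)
        ev = g.copy_with(g.values * 1.03)
        gamma = gamma_index(g, ev)
        assert passing_rate(gamma) == 100.0

    def test_flat_five_percent_offset_fails_everywhere(self):
        flat = sr.VoxelGrid(values=np.full((8, 8, 8), 10.0), spacing=(3, 3, 3))
        ev = flat.copy_with(flat.values * 1.05)
        gamma = gamma_index(flat, ev)
        # distance search cannot reduce the dose term on a flat field
        assert np.nanmin(gamma) == pytest.approx(5.0 / 3.0, rel=1e-6)
        assert passing_rate(gamma) == 0.0

    def test_local_normalization_scale_invariance(self, rng):
        ref = smooth_random_grid(rng)
        ev = ref.copy_with(ref.values * (1 + 0.02 * np.sin(np.arange(400).reshape(10, 10, 4))))
        g1 = gamma_index(ref, ev)
        g2 = gamma_index(ref.copy_with(ref.values * 7.0), ev.copy_with(ev.values * 7.0))
        assert np.allclose(g1, g2, equal_nan=True, atol=1e-9)

    def test_gamma_monotone_as_criteria_loosen(self, rng):
        ref = smooth_random_grid(rng)
        noise = 1.0 + 0.04 * np.cos(np.arange(400).reshape(10, 10, 4))
        ev = ref.copy_with(ref.values * noise)
        # fixed sampling lattice so the offset sets are nested
        tight = gamma_index(ref, ev, GammaCriteria(dose_pct=3, distance_mm=3,
                                                   interp_step_mm=1.0))
        loose_d = gamma_index(ref, ev, GammaCriteria(dose_pct=5, distance_mm=3,
                                                     interp_step_mm=1.0))
        loose_r = gamma_index(ref, ev, GammaCriteria(dose_pct=3, distance_mm=5,
                                                     interp_step_mm=1.0))
        assert np.all((loose_d <= tight + 1e-9) | np.isnan(tight))
        assert np.all((loose_r <= tight + 1e-9) | np.isnan(tight))

    def test_agrees_with_brute_force_oracle(self, rng):
        crit = GammaCriteria(dose_pct=3, distance_mm=3,
                             interp_step_mm=0.3)  # oracle-matched fine step
        ref = smooth_random_grid(rng, shape=(8, 8, 3))
        ev = ref.copy_with(
            ref.values * (1.0 + rng.normal(0.0, 0.02, ref.shape))
        )
        mine = gamma_index(ref, ev, crit)
        oracle = brute_force_gamma(ref, ev, crit)
        rate_mine = passing_rate(mine)
        rate_oracle = 100.0 * np.nanmean(oracle[np.isfinite(oracle)] <= 1.0 + 1e-6)
        assert abs(rate_mine - rate_oracle) <= 0.5

    def test_all_below_threshold_rejected(self):
        z = sr.VoxelGrid(values=np.zeros((4, 4, 4)), spacing=(3, 3, 3))
        with pytest.raises(ValueError, match="evaluable"):
            gamma_index(z, z)


class TestPassingRate:
    def test_counting(self):
        g = np.zeros((4, 4, 4))
        assert passing_rate(g) == 100.0
        g = np.concatenate([np.full(32, 0.5), np.full(32, 1.5)]).reshape(4, 4, 4)
        assert passing_rate(g) == 50.0

    def test_random_grid_vs_counting_oracle(self, rng):
        g = rng.random((5, 5, 5)) * 2.0
        g[0, 0, 0] = np.nan  # excluded voxel
        expected = 100.0 * np.sum(g[np.isfinite(g)] <= 1.0 + 1e-6) / np.isfinite(g).sum()
        assert passing_rate(g) == pytest.approx(expected)

    def test_mask_restriction_and_empty_error(self):
        g = np.full((2, 2, 2), 0.5)
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        assert passing_rate(g, mask) == 100.0
        with pytest.raises(ValueError):
            passing_rate(g, np.zeros((2, 2, 2), bool))


def test_compare_distributions_end_to_end(rng):
    ref = smooth_random_grid(rng)
    ev = ref.copy_with(ref.values * 1.01)
    res = compare_distributions(ref, ev)
    assert res.delta_pct == pytest.approx(1.0, abs=1e-9)
    assert res.gamma_pass_rate_pct == 100.0
    assert res.n_evaluable > 0
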