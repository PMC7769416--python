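import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scatterrisk as sr
from scatterrisk.dosimetry import (
    compute_dvh,
    default_bin_edges,
    organ_stats,
    rescale_to_prescription,
)
from scatterrisk.plans import Beam, Plan
from scatterrisk.risk import oed_linear

from conftest import make_dose_grid


def uniform_dose(value, shape=(4, 4, 4), rel_unc=0.0):
    return make_dose_grid(
        np.full(shape, float(value)), rel_unc=np.full(shape, rel_unc)
    )


def toy_plan(n_beams=1, prescription=50.0, spec_points=None):
    beams = [
        Beam(energy_label="1.0MeV", gantry_deg=0.0, isocenter_mm=(8, 8, 8),
             field_size_mm=(10, 10))
        for _ in range(n_beams)
    ]
    return Plan(beams=beams, prescription_gy=prescription,
                specification_point_mm=(8.0, 8.0, 8.0),
                beam_spec_points_mm=spec_points, name="toy")


class TestRescale:
    def test_relative_half_gives_factor_100(self):
        dose, scales = rescale_to_prescription([uniform_dose(0.5)], toy_plan())
        assert scales[0] == pytest.approx(100.0)
        assert dose.dose.value_at((8, 8, 8)) == pytest.approx(50.0, rel=1e-6)

    def test_already_calibrated_factor_one(self):
        dose, scales = rescale_to_prescription([uniform_dose(50.0)], toy_plan())
        assert scales[0] == pytest.approx(1.0)

    def test_two_beams_equal_shares_each_give_half_prescription(self):
        # hand computation: each beam delivers 25 Gy at its own spec point
        a, b = uniform_dose(2.0), uniform_dose(10.0)
        plan = toy_plan(n_beams=2)
        dose, scales = rescale_to_prescription([a, b], plan)
        assert scales[0] == pytest.approx(25.0 / 2.0)
        assert scales[1] == pytest.approx(25.0 / 10.0)
        assert dose.dose.value_at((8, 8, 8)) == pytest.approx(50.0, rel=1e-6)

    def test_relative_uncertainty_unchanged_by_scaling(self):
        g = uniform_dose(0.5, rel_unc=0.03)
        dose, _ = rescale_to_prescription([g], toy_plan())
        assert np.allclose(dose.rel_uncertainty.values, 0.03)

    def test_zero_dose_at_spec_point_rejected(self):
        with pytest.raises(ValueError, match="specification point"):
            rescale_to_prescription([uniform_dose(0.0)], toy_plan())


class TestDVH:
    def test_uniform_organ_single_bin(self):
        dg = uniform_dose(2.0)
        mask = np.ones((4, 4, 4), dtype=bool)
        dvh = compute_dvh(dg, mask, bin_width_gy=0.1)
        assert int((dvh.volumes > 0).sum()) == 1
        edges, cum = dvh.cumulative()
        # V(>=2 Gy) = 100%, V(>=2.1 Gy) = 0%
        assert cum[np.searchsorted(edges, 2.0)] == pytest.approx(100.0)
        assert cum[np.searchsorted(edges, 2.1)] == pytest.approx(0.0)

    def test_bins_match_counting_oracle(self, rng):
        vals = rng.random((6, 6, 6)) * 5.0
        dg = make_dose_grid(vals)
        mask = rng.random((6, 6, 6)) > 0.3
        w = 0.25
        dvh = compute_dvh(dg, mask, bin_width_gy=w)
        organ = vals[mask]
        for i in range(dvh.n_bins):
            lo, hi = dvh.edges_gy[i], dvh.edges_gy[i + 1]
            assert dvh.volumes[i] == np.sum((organ >= lo) & (organ < hi))
        assert dvh.total_volume == organ.size  # sums exactly

    def test_mean_from_bins_within_half_bin_of_voxel_mean(self, rng):
        vals = rng.random((6, 6, 6)) * 3.0
        dg = make_dose_grid(vals)
        mask = np.ones(vals.shape, dtype=bool)
        for w in (0.2, 0.1):
            dvh = compute_dvh(dg, mask, bin_width_gy=w)
            assert abs(dvh.mean_dose() - vals.mean()) <= w / 2.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_cumulative_dvh_monotone_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(0.5, 2.0, size=(5, 5, 5))
        dvh = compute_dvh(make_dose_grid(vals), np.ones((5, 5, 5), bool),
                          bin_width_gy=0.3)
        _, cum = dvh.cumulative()
        assert np.all(np.diff(cum) <= 1e-12)
        assert cum[0] == pytest.approx(100.0)

    def test_empty_mask_and_geometry_mismatch(self):
        dg = uniform_dose(1.0)
        with pytest.raises(ValueError, match="empty"):
            compute_dvh(dg, np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError, match="geometry"):
            compute_dvh(dg, np.ones((3, 3, 3), bool))

    def test_default_edges_cover_maximum(self):
        for top in (0.05, 1.999, 2.0, 7.3):
            edges = default_bin_edges(top)
            assert edges[-1] > top
            assert np.all(np.diff(edges) > 0)


class TestOrganStats:
    def test_hand_quadrature_example(self):
        # 8 voxels of 1 Gy with 2% relative sigma: mean CI = 0.02/sqrt(8)
        dg = uniform_dose(1.0, shape=(2, 2, 2), rel_unc=0.02)
        st_ = organ_stats(dg, np.ones((2, 2, 2), bool))
        assert st_.mean_gy == pytest.approx(1.0)
        assert st_.max_gy == pytest.approx(1.0)
        assert st_.mean_ci_gy == pytest.approx(0.02 / np.sqrt(8.0), rel=1e-9)
        assert st_.max_ci_gy == pytest.approx(0.02)

    def test_zero_uncertainty_grid_gives_zero_cis(self, rng):
        dg = make_dose_grid(rng.random((3, 3, 3)))
        st_ = organ_stats(dg, np.ones((3, 3, 3), bool))
        assert st_.mean_ci_gy == 0.0 and st_.max_ci_gy == 0.0

    def test_mean_equals_linear_oed_of_fine_dvh(self, rng):
        vals = rng.random((5, 5, 5)) * 2.0
        dg = make_dose_grid(vals)
        mask = np.ones(vals.shape, bool)
        st_ = organ_stats(dg, mask)
        w = 0.002
        oed = oed_linear(compute_dvh(dg, mask, bin_width_gy=w))
        assert abs(oed.oed_gy - st_.mean_gy) <= w / 2.0

    def test_stats_scale_linearly_with_dose(self, rng):
        vals = rng.random((4, 4, 4)) + 0.1
        unc = rng.random((4, 4, 4)) * 0.05
        a = organ_stats(make_dose_grid(vals, rel_unc=unc), np.ones((4, 4, 4), bool))
        b = organ_stats(make_dose_grid(3 * vals, rel_unc=unc), np.ones((4, 4, 4), bool))
        for field in ("mean_gy", "max_gy", "mean_ci_gy", "max_ci_gy"):
            assert getattr(b, field) == pytest.approx(3 * getattr(a, field), rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            organ_stats(uniform_dose(1.0), np.zeros((4, 4, 4), bool))
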