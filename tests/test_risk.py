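import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scatterrisk.dosimetry import DVH, OrganStats
from scatterrisk.risk import (
    RiskCoefficient,
    RiskModelConfig,
    default_risk_coefficients,
    ear,
    ear_ci,
    oed_linear,
    oed_linexp,
    risk_table,
    select_model,
)


def uniform_dvh(dose, volume=100.0, organ="organ"):
    w = 0.01
    lo = np.floor(dose / w) * w
    return DVH(organ=organ, edges_gy=np.array([lo, lo + w]),
               volumes=np.array([volume]), voxel_volume_mm3=8.0)


def two_level_dvh(d1, v1, d2, v2):
    """Two occupied narrow bins at doses d1 and d2."""
    eps = 1e-9
    edges = sorted({0.0, d1, d1 + eps, d2, d2 + eps})
    edges = np.array(edges)
    vols = np.zeros(len(edges) - 1)
    for d, v in ((d1, v1), (d2, v2)):
        i = np.searchsorted(edges, d, side="right") - 1
        vols[i] += v
    return DVH(organ="organ", edges_gy=edges, volumes=vols, voxel_volume_mm3=8.0)


class TestOED:
    def test_linear_uniform_and_mixture(self):
        assert oed_linear(uniform_dvh(2.0)).oed_gy == pytest.approx(2.0, abs=0.005)
        mix = two_level_dvh(1.0, 50.0, 3.0, 50.0)
        assert oed_linear(mix).oed_gy == pytest.approx(2.0, abs=1e-6)

    def test_linear_oed_is_mean_dose_of_fine_dvh(self):
        # an organ whose voxel mean is 0.277 Gy has linear OED 0.277 Gy
        rng = np.random.default_rng(1)
        vals = np.clip(rng.normal(0.277, 0.05, 4000), 0.0, None)
        vals *= 0.277 / vals.mean()
        w = 1e-4
        edges = np.arange(0, vals.max() + 2 * w, w)
        idx = np.searchsorted(edges, vals, side="right") - 1
        dvh = DVH(organ="contralateral breast", edges_gy=edges,
                  volumes=np.bincount(idx, minlength=len(edges) - 1).astype(float),
                  voxel_volume_mm3=8.0)
        assert oed_linear(dvh).oed_gy == pytest.approx(0.277, abs=w)

    def test_linexp_closed_forms(self):
        # uniform 2 Gy: 2 exp(-0.088)
        got = oed_linexp(uniform_dvh(2.0)).oed_gy
        assert got == pytest.approx(2.0 * np.exp(-0.088), abs=0.01)
        # exact on an exactly-centered bin
        dvh = DVH(organ="o", edges_gy=np.array([1.995, 2.005]),
                  volumes=np.array([10.0]), voxel_volume_mm3=8.0)
        assert oed_linexp(dvh).oed_gy == pytest.approx(2.0 * np.exp(-0.088), rel=1e-9)
        # half volume at 10 Gy, half at 0: 0.5 * 10 exp(-0.44)
        mix = two_level_dvh(0.0, 50.0, 10.0, 50.0)
        assert oed_linexp(mix).oed_gy == pytest.approx(
            0.5 * 10.0 * np.exp(-0.44), rel=1e-6
        )

    def test_alpha_zero_reduces_to_linear_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            edges = np.sort(rng.random(12)) * 10
            edges = np.unique(edges)
            dvh = DVH(organ="o", edges_gy=edges,
                      volumes=rng.random(len(edges) - 1) * 50,
                      voxel_volume_mm3=8.0)
            a = oed_linexp(dvh, RiskModelConfig(alpha_per_gy=0.0)).oed_gy
            b = oed_linear(dvh).oed_gy
            assert abs(a - b) < 1e-12

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_linexp_never_exceeds_linear(self, seed):
        rng = np.random.default_rng(seed)
        edges = np.unique(np.concatenate([[0.0], np.sort(rng.random(10)) * 60]))
        dvh = DVH(organ="o", edges_gy=edges,
                  volumes=rng.random(len(edges) - 1) * 100,
                  voxel_volume_mm3=8.0)
        if dvh.total_volume == 0:
            return
        assert oed_linexp(dvh).oed_gy <= oed_linear(dvh).oed_gy + 1e-12

    def test_zero_volume_rejected(self):
        dvh = DVH(organ="o", edges_gy=np.array([0.0, 1.0]),
                  volumes=np.array([0.0]), voxel_volume_mm3=8.0)
        with pytest.raises(ValueError):
            oed_linear(dvh)


class TestModelSelection:
    @pytest.mark.parametrize(
        "mean,expected",
        [
            (19.234, "linear-exponential"),  # in-field thyroid regime
            (0.277, "linear"),  # out-of-field breast regime
            (2.0, "linear"),  # boundary: strict inequality
            (2.0001, "linear-exponential"),
        ],
    )
    def test_mean_dose_threshold(self, mean, expected):
        stats = OrganStats(organ="o", mean_gy=mean, max_gy=mean + 1,
                           mean_ci_gy=0.0, max_ci_gy=0.0, n_voxels=10)
        assert select_model(stats) == expected


class TestEAR:
    def test_identities(self):
        c = RiskCoefficient(organ="o", exposure_age=30, ear0=1.0)
        from scatterrisk.risk import OEDResult

        assert ear(OEDResult("o", "linear", 0.0), c).ear == 0.0
        assert ear(OEDResult("o", "linear", 0.7), c).ear == pytest.approx(0.7)

    def test_calibrated_from_printed_pair(self):
        # coefficient calibrated as 2.55 / 0.277 applied to 0.428 Gy -> 3.94
        from scatterrisk.risk import OEDResult

        c = RiskCoefficient(organ="contralateral breast", exposure_age=30,
                            ear0=2.55 / 0.277)
        res = ear(OEDResult("contralateral breast", "linear", 0.428), c)
        assert res.ear == pytest.approx(3.94, abs=0.01)

    def test_ci_scaling_and_clamp(self):
        from scatterrisk.risk import OEDResult

        c = RiskCoefficient(organ="o", exposure_age=50, ear0=0.4, ci90=(0.0, 1.3))
        lo, hi = ear_ci(OEDResult("o", "linear", 2.0), c)
        assert lo == 0.0 and hi == pytest.approx(2.6)
        lo2, hi2 = ear_ci(OEDResult("o", "linear", 4.0), c)
        assert hi2 == pytest.approx(2 * hi)
        z = RiskCoefficient(organ="o", exposure_age=30, ear0=0.0, ci90=(0.0, 0.0))
        assert ear_ci(OEDResult("o", "linear", 5.0), z) == (0.0, 0.0)

    def test_missing_ci_still_reports_ear(self):
        from scatterrisk.risk import OEDResult

        c = RiskCoefficient(organ="o", exposure_age=30, ear0=2.0, ci90=None)
        res = ear(OEDResult("o", "linear", 1.5), c)
        assert res.ear == pytest.approx(3.0)
        assert res.ci90 is None


class TestRiskTable:
    def stats_for(self, name, mean):
        return OrganStats(organ=name, mean_gy=mean, max_gy=mean * 1.5,
                          mean_ci_gy=0.0, max_ci_gy=0.0, n_voxels=8)

    def test_single_organ_row_equals_direct_composition(self):
        dvh = uniform_dvh(0.5, organ="stomach")
        coeffs = [RiskCoefficient(organ="stomach", exposure_age=30, ear0=9.5,
                                  ci90=(6.1, 14.0))]
        df = risk_table([(self.stats_for("stomach", 0.5), dvh)], coeffs)
        row = df.iloc[0]
        direct = ear(oed_linear(dvh), coeffs[0])
        assert row["ear_per_10k_py"] == pytest.approx(direct.ear)
        assert row["model"] == "linear"

    def test_linear_regime_ear_scales_with_mean_dose(self):
        # stomach between the two plan intensities: EAR ratio = dose ratio
        coeffs = [RiskCoefficient(organ="stomach", exposure_age=30, ear0=9.5)]
        rows = []
        for mean in (0.498, 1.387):
            dvh = uniform_dvh(mean, organ="stomach")
            df = risk_table([(self.stats_for("stomach", mean), dvh)], coeffs)
            rows.append(df.iloc[0]["ear_per_10k_py"])
        assert rows[1] / rows[0] == pytest.approx(1.387 / 0.498, rel=0.02)

    def test_organ_without_coefficient_listed_blank(self):
        dvh = uniform_dvh(0.1, organ="spleen")
        coeffs = [RiskCoefficient(organ="stomach", exposure_age=30, ear0=9.5)]
        df = risk_table([(self.stats_for("spleen", 0.1), dvh)], coeffs)
        assert len(df) == 1
        assert np.isnan(df.iloc[0]["ear_per_10k_py"])


def test_shipped_coefficient_table_loads_and_validates():
    coeffs = default_risk_coefficients()
    assert len(coeffs) > 15
    sites = {c.organ for c in coeffs}
    assert {"breast", "stomach", "lung", "thyroid", "colon"} <= sites
    for c in coeffs:
        assert c.ear0 >= 0
        if c.ci90:
            assert c.ci90[0] <= c.ear0 <= c.ci90[1]
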