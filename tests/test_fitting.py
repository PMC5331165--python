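"""Sector fitting, global DV, study orchestration, extraction calibration."""

import dataclasses

import numpy as np
import pytest

from rbflow.fitting import (
    DELAY_COMBINATION,
    FitConfig,
    SectorFit,
    calibrate_extraction,
    estimate_global_dv,
    fit_sector,
    fit_study,
    nonconvergence_rate,
)
from rbflow.model import (
    TAC,
    KineticParams,
    ModelVariant,
    PolarMap,
    REFERENCE_VARIANT,
    frame_average,
    tissue_curve,
)
from rbflow.synthetic import SyntheticStudyConfig, make_study

REGIONAL = ModelVariant(soc=False, rbc=False, roi="blood", dv="regional", delay=False)
GLOBAL = ModelVariant(soc=False, rbc=False, roi="blood", dv="global", delay=False)


@pytest.fixture(scope="module")
def sector_truth(grid_mod, bolus_curve_mod, bolus_tac_mod):
    tis = frame_average(tissue_curve(KineticParams(k1=0.8, dv=0.9), bolus_curve_mod), grid_mod)
    cmyo = TAC(grid_mod, 0.25 * bolus_tac_mod.values + 0.75 * tis.values)
    return cmyo, bolus_tac_mod


# re-expose session fixtures at module scope for the fixture above
@pytest.fixture(scope="module")
def grid_mod(request):
    from rbflow.model import default_grid

    return default_grid()


@pytest.fixture(scope="module")
def bolus_curve_mod(grid_mod):
    import numpy as np

    from rbflow.model import ContinuousCurve
    from rbflow.synthetic import _bolus_with_recirc

    t = np.arange(0, grid_mod.end + 1e-9, 0.1)
    return ContinuousCurve(0.1, _bolus_with_recirc(t, 100.0, 5.0, 3.0, 8.0, 0.15, 40.0))


@pytest.fixture(scope="module")
def bolus_tac_mod(grid_mod, bolus_curve_mod):
    return frame_average(bolus_curve_mod, grid_mod)


class TestFitSector:
    def test_regional_recovery_noise_free(self, sector_truth):
        cmyo, blood = sector_truth
        fit = fit_sector(cmyo, blood, None, REGIONAL, None, septal=False)
        assert fit.converged
        assert fit.params.k1 == pytest.approx(0.8, rel=0.01)
        assert fit.params.fbv == pytest.approx(0.25, rel=0.01)
        assert fit.params.dv == pytest.approx(0.9, rel=0.01)

    def test_global_dv_recovery(self, sector_truth):
        cmyo, blood = sector_truth
        fit = fit_sector(cmyo, blood, None, GLOBAL, 0.9, septal=False)
        assert fit.params.k1 == pytest.approx(0.8, rel=0.01)

    def test_rbc_off_septum_keeps_rvbv_zero(self, sector_truth):
        cmyo, blood = sector_truth
        rbc = dataclasses.replace(GLOBAL, rbc=True)
        fit = fit_sector(cmyo, blood, blood, rbc, 0.9, septal=False)
        assert fit.params.rvbv == 0.0
        assert "rvbv" not in fit.boundary_hits

    def test_all_zero_sector_flagged_degenerate(self, sector_truth):
        _, blood = sector_truth
        zero = TAC(blood.grid, np.zeros(blood.grid.n_frames))
        fit = fit_sector(zero, blood, None, GLOBAL, 0.9, septal=False)
        assert fit.degenerate and not fit.converged

    def test_contract_violations_raise(self, sector_truth):
        cmyo, blood = sector_truth
        with pytest.raises(ValueError):
            fit_sector(cmyo, blood, None, GLOBAL, None, septal=False)  # missing global DV
        with pytest.raises(ValueError):
            fit_sector(cmyo, blood, None, dataclasses.replace(GLOBAL, rbc=True), 0.9, septal=True)

    def test_free_dv_never_fits_worse_than_fixed(self, sector_truth):
        """Nesting: the regional model contains the global-DV model."""
        cmyo, blood = sector_truth
        rng = np.random.default_rng(0)
        noisy = TAC(cmyo.grid, cmyo.values * (1 + 0.03 * rng.standard_normal(14)))
        wrss_fixed = fit_sector(noisy, blood, None, GLOBAL, 0.9, septal=False).wrss
        wrss_free = fit_sector(noisy, blood, None, REGIONAL, None, septal=False).wrss
        assert wrss_free <= wrss_fixed * (1 + 1e-6)


class TestGlobalDV:
    def test_homogeneous_map_recovers_dv(self, clean_config):
        study = make_study(clean_config, seed=2)
        scan = study.get("rest", "test")
        dv = estimate_global_dv(scan.polar, study.true_inputs[("rest", "test")])
        assert dv == pytest.approx(clean_config.dv, rel=0.01)

    def test_uniform_uptake_keeps_all_sectors(self, sector_truth):
        cmyo, blood = sector_truth
        vals = np.tile(cmyo.values, (20, 1))
        polar = PolarMap(cmyo.grid, vals, np.array(["LAD"] * 20), np.zeros(20, bool))
        assert np.sum(polar.uptake > 0.75 * polar.uptake.max()) == 20

    def test_low_uptake_region_excluded(self, sector_truth):
        cmyo, blood = sector_truth
        vals = np.tile(cmyo.values, (10, 1))
        vals[:3] *= 0.5  # defect at 50% of maximum uptake
        polar = PolarMap(cmyo.grid, vals, np.array(["LAD"] * 10), np.zeros(10, bool))
        qualifying = polar.uptake > 0.75 * polar.uptake.max()
        assert qualifying.sum() == 7 and not qualifying[:3].any()


class TestFitStudy:
    def test_mfr_and_delta_from_doubled_stress(self):
        cfg = SyntheticStudyConfig(
            n_sectors=24,
            noise=0.0,
            jitter_cv=0.0,
            bolus_jitter_cv=0.0,
            beta_scan_jitter_sd=0.0,
            rvbv_septal=0.0,
            transport_delay_s=0.0,
            rest_mbf={"LAD": 0.9, "LCX": 0.9, "RCA": 0.9},
            stress_mbf={"LAD": 1.8, "LCX": 1.8, "RCA": 1.8},
        )
        study = make_study(cfg, seed=3)
        flows = fit_study(study, REFERENCE_VARIANT)
        for terr, mfr in flows.mfr("test").items():
            assert mfr == pytest.approx(2.0, rel=0.03)
        rest = flows.territory_mbf("rest", "test")
        stress = flows.territory_mbf("stress", "test")
        for terr, d in flows.delta_mbf("test").items():
            assert d == pytest.approx(stress[terr] - rest[terr], abs=1e-12)

    def test_delay_gated_to_reference_combination(self, clean_config):
        study = make_study(clean_config, seed=4)
        bad = dataclasses.replace(DELAY_COMBINATION, roi="uptake")
        with pytest.raises(ValueError, match="delay"):
            fit_study(study, bad)
        fit_study(study, bad, FitConfig(allow_delay_any_variant=True, n_multistart=1))


class TestCalibrateExtraction:
    @pytest.mark.parametrize("a,b", [(0.76, 0.40), (0.77, 0.63)])
    def test_recovers_generating_coefficients(self, a, b):
        mbf = np.linspace(0.3, 3.0, 25)
        k1 = (1 - a * np.exp(-b / mbf)) * mbf
        ext = calibrate_extraction(mbf, k1)
        assert ext.a == pytest.approx(a, abs=0.01)
        assert ext.b == pytest.approx(b, abs=0.01)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            calibrate_extraction(np.full(12, 1.0), np.full(12, 0.5))
        with pytest.raises(ValueError):
            calibrate_extraction(np.linspace(-1, 1, 12), np.linspace(0.1, 1, 12))
        with pytest.raises(ValueError):
            calibrate_extraction([1.0, 2.0], [0.5, 0.9])  # too few pairs


class TestNonconvergence:
    def _fit(self, hits, ok=True):
        return SectorFit(0, KineticParams(k1=0.5, dv=1.0), 0.0, ok and not any(hits.values()), hits)

    def test_all_converged_is_zero(self):
        fits = [self._fit({"delay": False}) for _ in range(4)]
        assert nonconvergence_rate(fits, "delay") == 0.0

    def test_fraction_arithmetic(self):
        fits = [self._fit({"delay": i == 0}) for i in range(4)]
        assert nonconvergence_rate(fits, "delay") == 0.25

    def test_any_includes_optimizer_failure(self):
        fits = [self._fit({}, ok=False), self._fit({})]
        assert nonconvergence_rate(fits, "any") == 0.5

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            nonconvergence_rate([], "any")
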