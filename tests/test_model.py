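"""Core kinetic model: grids, convolution, mixing, extraction, variants."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from rbflow.model import (
    LORTIE,
    SOC_ON_EXTRACTION,
    TAC,
    ContinuousCurve,
    ExtractionFunction,
    GridMismatchError,
    InputDomainError,
    KineticParams,
    ModelVariant,
    ParameterError,
    REFERENCE_VARIANT,
    TimeGrid,
    default_grid,
    frame_average,
    k1_of_mbf,
    mbf_of_k1,
    mix_lv,
    mix_lv_rv,
    tissue_response,
    variant_catalog,
)
from rbflow.qa import gamma_variate


def riemann_tissue_oracle(params, blood_fn, grid, step=0.01):
    """Brute-force discrete convolution of the kinetic model at a fine step."""
    t = np.arange(0.0, grid.end + step / 2, step)
    f = blood_fn(t)
    kernel = (params.k1 / 60.0) * np.exp(-(params.k2 / 60.0) * t)
    y = fftconvolve(f, kernel)[: t.size] * step
    y -= 0.5 * step * (f * kernel[0] + f[0] * kernel)  # trapezoid endpoint correction
    if params.delay > 0:
        y = np.interp(t - params.delay, t, y, left=0.0)
    cum = np.concatenate(([0.0], np.cumsum((y[1:] + y[:-1]) / 2.0) * step))
    lo = np.interp(grid.frame_start, t, cum)
    hi = np.interp(grid.frame_end, t, cum)
    return (hi - lo) / grid.frame_duration


class TestTimeGrid:
    def test_default_schedule(self, grid):
        assert grid.n_frames == 14
        assert grid.end == 360.0
        assert list(grid.frame_duration) == [10.0] * 9 + [30.0] * 3 + [60.0, 120.0]

    @pytest.mark.parametrize(
        "start,dur",
        [
            ([0.0, 5.0], [10.0, 10.0]),  # overlap
            ([0.0, 10.0], [10.0, -5.0]),  # nonpositive duration
            ([-1.0, 9.0], [10.0, 10.0]),  # negative origin
        ],
    )
    def test_rejects_malformed_schedules(self, start, dur):
        with pytest.raises(ValueError):
            TimeGrid(np.array(start), np.array(dur))

    def test_tac_length_must_match(self, grid):
        with pytest.raises(ValueError):
            TAC(grid, np.zeros(grid.n_frames - 1))

    def test_rebin_matches_direct_frame_average(self, grid, bolus_curve):
        from rbflow.model import fine_grid, rebin

        fine = frame_average(bolus_curve, fine_grid(1.0, 360.0))
        np.testing.assert_allclose(
            rebin(fine, grid).values, frame_average(bolus_curve, grid).values, rtol=1e-12
        )

    def test_rebin_rejects_misaligned_target(self, grid, bolus_curve):
        from rbflow.model import fine_grid, rebin

        fine = frame_average(bolus_curve, fine_grid(7.0, 357.0))
        with pytest.raises(GridMismatchError):
            rebin(fine, grid)


class TestTissueResponse:
    def test_zero_uptake_gives_zero_tac(self, grid, bolus_curve):
        tac = tissue_response(KineticParams(k1=0.0, dv=1.0), bolus_curve, grid)
        assert np.all(tac.values == 0)

    def test_constant_input_saturates_at_dv(self):
        """With constant blood, tissue/blood -> DV once t >> 1/k2."""
        params = KineticParams(k1=0.8, dv=0.9)
        c0 = 10.0
        blood = ContinuousCurve(0.1, np.full(12001, c0))  # 20 min
        grid = TimeGrid(np.array([0.0, 600.0]), np.array([600.0, 600.0]))
        tac = tissue_response(params, blood, grid)
        # closed form: DV * C0 * (1 - exp(-k2 t)), frame-averaged
        k = params.k2 / 60.0
        t = np.arange(0, 1200.01, 0.1)
        expected = params.dv * c0 * (1 - np.exp(-k * t))
        cum = np.concatenate(([0], np.cumsum((expected[1:] + expected[:-1]) / 2) * 0.1))
        exp_frames = np.diff(np.interp([0, 600, 1200], t, cum)) / 600.0
        np.testing.assert_allclose(tac.values, exp_frames, rtol=1e-4)
        # equilibrium property at t > 5 / k2
        assert abs(tac.values[-1] / c0 / params.dv - 1) < 0.005

    def test_matches_riemann_oracle_on_random_draws(self, grid):
        rng = np.random.default_rng(42)
        blood_fn = lambda t: gamma_variate(t, 100.0, 5.0, 3.0, 8.0)
        blood = ContinuousCurve.from_function(blood_fn, grid.end, 0.1)
        for _ in range(30):
            params = KineticParams(
                k1=rng.uniform(0.2, 2.0),
                dv=rng.uniform(0.4, 2.0),
                delay=rng.uniform(0.0, 8.0),
            )
            got = tissue_response(params, blood, grid).values
            want = riemann_tissue_oracle(params, blood_fn, grid)
            # relative per frame, floored at 0.5% of the peak so near-zero
            # onset frames compare on an absolute scale
            err = np.abs(got - want) / np.maximum(np.abs(want), 5e-3 * want.max())
            assert err.max() < 1e-3

    def test_delay_zeroes_frames_before_onset(self, grid, bolus_curve):
        tac = tissue_response(KineticParams(k1=0.5, dv=1.0, delay=10.0), bolus_curve, grid)
        assert tac.values[0] == 0.0  # frame [0, 10] ends at the delay

    def test_grid_beyond_curve_raises(self, bolus_curve):
        long_grid = TimeGrid(np.array([0.0]), np.array([500.0]))
        with pytest.raises(InputDomainError):
            tissue_response(KineticParams(k1=0.5, dv=1.0), bolus_curve, long_grid)


class TestMixing:
    def test_endmember_weights(self, bolus_tac, tissue_tac):
        np.testing.assert_array_equal(mix_lv(tissue_tac, bolus_tac, 0.0).values, tissue_tac.values)
        np.testing.assert_array_equal(mix_lv(tissue_tac, bolus_tac, 1.0).values, bolus_tac.values)

    def test_lv_arithmetic(self, grid):
        tissue = TAC(grid, np.ones(14))
        blood = TAC(grid, 2 * np.ones(14))
        np.testing.assert_allclose(mix_lv(tissue, blood, 0.3).values, 1.3)

    def test_lv_rv_arithmetic(self, grid):
        t, b, r = (TAC(grid, v * np.ones(14)) for v in (1.0, 2.0, 3.0))
        np.testing.assert_allclose(mix_lv_rv(t, b, r, 0.2, 0.1).values, 1.4)

    def test_rv_zero_reduces_to_lv_mixing(self, bolus_tac, tissue_tac):
        rv = TAC(bolus_tac.grid, np.zeros(14))
        a = mix_lv_rv(tissue_tac, bolus_tac, rv, 0.3, 0.0)
        b = mix_lv(tissue_tac, bolus_tac, 0.3)
        np.testing.assert_allclose(a.values, b.values)

    def test_weights_conserve_constant_signals(self, grid):
        c = TAC(grid, 7.0 * np.ones(14))
        np.testing.assert_allclose(mix_lv_rv(c, c, c, 0.25, 0.15).values, 7.0)

    def test_invalid_weights_raise(self, bolus_tac, tissue_tac):
        with pytest.raises(ParameterError):
            mix_lv(tissue_tac, bolus_tac, 1.5)
        with pytest.raises(ParameterError):
            mix_lv_rv(tissue_tac, bolus_tac, bolus_tac, 0.7, 0.5)

    def test_grid_mismatch_raises(self, bolus_tac):
        other = TAC(TimeGrid(np.array([0.0]), np.array([10.0])), np.array([1.0]))
        with pytest.raises(GridMismatchError):
            mix_lv(other, bolus_tac, 0.2)


class TestExtraction:
    def test_low_flow_extraction_limit(self):
        assert k1_of_mbf(1e-6) / 1e-6 == pytest.approx(1.0, abs=1e-3)

    def test_high_flow_plateau(self):
        assert k1_of_mbf(1e6) / 1e6 == pytest.approx(1 - LORTIE.a, rel=1e-4)

    def test_direct_evaluation(self):
        assert k1_of_mbf(1.0, LORTIE) == pytest.approx((1 - 0.77 * np.exp(-0.63)) * 1.0)

    @pytest.mark.parametrize("x", [0.3, 1.0, 3.0])
    @pytest.mark.parametrize("ext", [LORTIE, SOC_ON_EXTRACTION])
    def test_roundtrip_identity(self, x, ext):
        assert mbf_of_k1(k1_of_mbf(x, ext), ext) == pytest.approx(x, abs=1e-6)

    def test_inverse_matches_bisection_oracle(self):
        k1 = 0.5
        lo, hi = 0.0, 50.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if k1_of_mbf(mid, LORTIE) < k1:
                lo = mid
            else:
                hi = mid
        assert mbf_of_k1(k1, LORTIE) == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_monotone_and_bounded_by_identity(self):
        mbf = np.linspace(0.01, 5.0, 200)
        k1 = k1_of_mbf(mbf, LORTIE)
        assert np.all(np.diff(k1) > 0)
        assert np.all(k1 <= mbf)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            k1_of_mbf(-0.1)
        with pytest.raises(ParameterError):
            mbf_of_k1(-0.1)
        with pytest.raises(ParameterError):
            ExtractionFunction(a=1.2, b=0.5)


class TestVariants:
    def test_full_factorial_counts(self):
        assert len(variant_catalog(True)) == 32
        assert len(variant_catalog(False)) == 16

    def test_no_duplicates(self):
        cat = variant_catalog(True)
        assert len(set(cat)) == len(cat)

    def test_parse_reference(self):
        v = ModelVariant.parse("soc=on,rbc=off,roi=blood,dv=global,delay=off")
        assert v == REFERENCE_VARIANT

    def test_parse_rejects_bad_string(self):
        with pytest.raises(ValueError):
            ModelVariant.parse("soc=maybe,rbc=off,roi=blood,dv=global,delay=off")

    def test_kinetic_params_validation(self):
        with pytest.raises(ParameterError):
            KineticParams(k1=0.5, dv=1.0, delay=11.0)
        with pytest.raises(ParameterError):
            KineticParams(k1=0.5, dv=1.0, fbv=0.8, rvbv=0.3)
        assert KineticParams(k1=0.6, dv=1.2).k2 == pytest.approx(0.5)
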