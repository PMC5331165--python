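"""Weighted nonlinear least-squares fitting of the model variants.

Every sector of the polar map is fit independently: the free parameters are
always K1 and the LV blood fraction, plus — depending on the variant — the
right-ventricular blood fraction (septal sectors only), a regional
distribution volume, and the arterial transport delay.  Washout is tied to
the distribution volume through k2 = K1 / DV.  Residuals are weighted by
frame duration, mirroring how count statistics scale with frame length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .model import (
    TAC,
    ContinuousCurve,
    ExtractionFunction,
    GridMismatchError,
    KineticParams,
    ModelVariant,
    ParameterError,
    PolarMap,
    REFERENCE_VARIANT,
    TERRITORIES,
    mbf_of_k1,
    tac_to_curve,
    tissue_response,
)
from .soc import SocConfig, WholeLVFit, soc_input

__all__ = [
    "FitConfig",
    "SectorFit",
    "FlowResult",
    "Scan",
    "Study",
    "StudyFlows",
    "fit_sector",
    "estimate_global_dv",
    "fit_study",
    "calibrate_extraction",
    "nonconvergence_rate",
]

#: The only delay-enabled combination fit by default; the delay parameter is
#: poorly identifiable at 10 s frames, so it is reported on the reference
#: combination only unless explicitly unlocked.
DELAY_COMBINATION = replace(REFERENCE_VARIANT, delay=True)


@dataclass(frozen=True)
class FitConfig:
    """Bounds, tolerances and policy for sector fits."""

    k1_bounds: tuple[float, float] = (0.01, 5.0)
    fbv_bounds: tuple[float, float] = (0.0, 1.0)
    rvbv_bounds: tuple[float, float] = (0.0, 0.5)
    dv_bounds: tuple[float, float] = (0.2, 5.0)
    delay_bounds: tuple[float, float] = (0.0, 10.0)
    xtol: float = 1e-8
    ftol: float = 1e-8
    n_multistart: int = 1
    seed: int = 0
    boundary_tol: float = 1e-3  # fraction of the bound range
    curve_step: float = 0.25  # input-curve step (s) used inside the fits
    soc: SocConfig = field(default_factory=SocConfig)
    allow_delay_any_variant: bool = False
    init_k1: float = 0.5
    init_fbv: float = 0.3
    init_dv: float = 1.0
    init_delay: float = 2.0


@dataclass
class SectorFit:
    """One sector's fit record."""

    sector_id: int
    params: KineticParams
    wrss: float
    converged: bool
    boundary_hits: dict[str, bool]
    degenerate: bool = False

    def hit(self, parameter: str) -> bool:
        return self.boundary_hits.get(parameter, False)


@dataclass
class FlowResult:
    """Per-scan flow map: sector MBF plus coronary-territory means."""

    condition: str
    repeat: str
    mbf_sector: np.ndarray
    territory_mbf: dict[str, float]
    fits: list[SectorFit]
    global_dv: float | None = None
    whole_lv_fit: WholeLVFit | None = None


@dataclass
class Scan:
    """One dynamic acquisition: sampled ROI TACs plus the sector polar map."""

    condition: str  # 'rest' | 'stress'
    repeat: str  # 'test' | 'retest'
    blood_roi: TAC
    uptake_roi: TAC
    whole_lv: TAC
    rv: TAC
    polar: PolarMap
    rpp: float = float("nan")


@dataclass
class Study:
    """Paired test-retest rest/stress scans for one subject."""

    subject_id: str
    scans: list[Scan]

    def get(self, condition: str, repeat: str) -> Scan:
        for s in self.scans:
            if s.condition == condition and s.repeat == repeat:
                return s
        raise KeyError(f"no scan for ({condition}, {repeat})")


@dataclass
class StudyFlows:
    """All four scans of one study fit with one model variant."""

    subject_id: str
    variant: ModelVariant
    results: dict[tuple[str, str], FlowResult]

    def territory_mbf(self, condition: str, repeat: str) -> dict[str, float]:
        return self.results[(condition, repeat)].territory_mbf

    def mfr(self, repeat: str) -> dict[str, float]:
        rest = self.territory_mbf("rest", repeat)
        stress = self.territory_mbf("stress", repeat)
        return {t: stress[t] / rest[t] for t in rest if rest[t] > 0}

    def delta_mbf(self, repeat: str) -> dict[str, float]:
        rest = self.territory_mbf("rest", repeat)
        stress = self.territory_mbf("stress", repeat)
        return {t: stress[t] - rest[t] for t in rest}

    def all_fits(self) -> list[SectorFit]:
        return [f for r in self.results.values() for f in r.fits]


# ---------------------------------------------------------------------------
# sector fit
# ---------------------------------------------------------------------------


def _free_parameters(variant: ModelVariant, septal: bool) -> list[str]:
    names = ["k1", "fbv"]
    if variant.rbc and septal:
        names.append("rvbv")
    if variant.dv == "regional":
        names.append("dv")
    if variant.delay:
        names.append("delay")
    return names


def fit_sector(
    c_myo: TAC,
    input_blood: TAC,
    c_rv: TAC | None,
    variant: ModelVariant,
    global_dv: float | None,
    septal: bool,
    config: FitConfig | None = None,
    sector_id: int = 0,
    input_curve: ContinuousCurve | None = None,
) -> SectorFit:
    """Fit one sector TAC with the requested model variant.

    ``global_dv`` must be given iff the variant uses a global DV; ``c_rv``
    iff right-blood correction is on.  ``input_curve`` may carry a
    precomputed fine-grid version of ``input_blood`` (shared across the
    sectors of one scan).
    """
    config = config or FitConfig()
    if c_myo.grid != input_blood.grid:
        raise GridMismatchError("myocardium and input TACs must share a grid")
    if (variant.dv == "global") != (global_dv is not None):
        raise ValueError("global_dv must be supplied exactly when variant.dv == 'global'")
    if variant.rbc and c_rv is None:
        raise ValueError("right-blood correction requires an RV TAC")
    if variant.rbc and c_rv is not None and c_rv.grid != c_myo.grid:
        raise GridMismatchError("RV TAC must share the sector grid")

    grid = c_myo.grid
    y = c_myo.values
    if not np.any(y != 0):
        params = KineticParams(k1=0.0, dv=global_dv or config.init_dv)
        return SectorFit(sector_id, params, 0.0, False, {}, degenerate=True)

    if input_curve is None:
        input_curve = tac_to_curve(input_blood, step=config.curve_step)
    blood_vals = input_blood.values
    rv_vals = c_rv.values if (variant.rbc and septal and c_rv is not None) else None

    names = _free_parameters(variant, septal)
    bounds_map = {
        "k1": config.k1_bounds,
        "fbv": config.fbv_bounds,
        "rvbv": config.rvbv_bounds,
        "dv": config.dv_bounds,
        "delay": config.delay_bounds,
    }
    init_map = {
        "k1": config.init_k1,
        "fbv": config.init_fbv,
        "rvbv": 0.05,
        "dv": config.init_dv,
        "delay": config.init_delay,
    }
    lo = np.array([bounds_map[n][0] for n in names])
    hi = np.array([bounds_map[n][1] for n in names])
    x0 = np.clip(np.array([init_map[n] for n in names]), lo, hi)
    w_sqrt = np.sqrt(grid.frame_duration)

    def unpack(x):
        d = dict(zip(names, x))
        k1 = d["k1"]
        dv = d.get("dv", global_dv)
        fbv = d["fbv"]
        rvbv = d.get("rvbv", 0.0)
        delay = d.get("delay", 0.0)
        return k1, dv, fbv, rvbv, delay

    def residuals(x):
        k1, dv, fbv, rvbv, delay = unpack(x)
        params = KineticParams(k1=k1, dv=dv, delay=min(delay, 10.0))
        tissue = tissue_response(params, input_curve, grid).values
        blood_frac = fbv + rvbv
        model = fbv * blood_vals + (1.0 - blood_frac) * tissue
        if rv_vals is not None:
            model = model + rvbv * rv_vals
        return w_sqrt * (model - y)

    rng = np.random.default_rng(config.seed + sector_id)
    starts = [x0]
    for _ in range(config.n_multistart - 1):
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    best = None
    for s in starts:
        try:
            sol = least_squares(residuals, s, bounds=(lo, hi), xtol=config.xtol, ftol=config.ftol)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        params = KineticParams(k1=0.0, dv=global_dv or config.init_dv)
        return SectorFit(sector_id, params, np.inf, False, {n: False for n in names})

    k1, dv, fbv, rvbv, delay = unpack(best.x)
    rvbv = min(rvbv, 1.0 - fbv)
    params = KineticParams(k1=k1, dv=dv, fbv=fbv, rvbv=rvbv, delay=min(delay, 10.0))
    hits = {
        n: bool(
            (best.x[i] - lo[i]) < config.boundary_tol * (hi[i] - lo[i])
            or (hi[i] - best.x[i]) < config.boundary_tol * (hi[i] - lo[i])
        )
        for i, n in enumerate(names)
    }
    converged = bool(best.success and not any(hits.values()))
    return SectorFit(sector_id, params, 2.0 * best.cost, converged, hits)


# ---------------------------------------------------------------------------
# global DV
# ---------------------------------------------------------------------------


def estimate_global_dv(
    polar: PolarMap, input_blood: TAC, config: FitConfig | None = None
) -> float:
    """DV of the normal-uptake region (> 75% of the polar-map maximum).

    The qualifying sectors' TACs are averaged into one low-noise TAC and the
    free (regional-DV) model is fit to it; the fitted DV is then fixed for
    every sector of the scan.
    """
    config = config or FitConfig()
    threshold = 0.75 * polar.uptake.max()
    mask = polar.uptake > threshold
    if not mask.any():
        raise ValueError("no sectors exceed 75% of the maximum uptake")
    mean_tac = TAC(polar.grid, polar.values[mask].mean(axis=0))
    variant = ModelVariant(soc=False, rbc=False, roi="blood", dv="regional", delay=False)
    fit = fit_sector(mean_tac, input_blood, None, variant, None, septal=False, config=config)
    return fit.params.dv


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------


def fit_study(
    study: Study,
    variant: ModelVariant,
    config: FitConfig | None = None,
    input_cache: dict | None = None,
) -> StudyFlows:
    """Fit every scan of a study with one model variant.

    Per scan: select the input TAC per the ROI switch, apply the dual
    spillover correction when enabled, estimate a global DV when enabled,
    fit all polar-map sectors, and convert K1 to MBF with the extraction
    function matched to the spillover setting.  Individual sector failures
    are recorded in the fit flags; the study never aborts.

    ``input_cache`` (optional, shared across variants) memoizes the
    spillover-corrected inputs and global-DV estimates, which depend only
    on the scan, the ROI choice and the SOC switch.
    """
    config = config or FitConfig()
    if variant.delay and not config.allow_delay_any_variant and variant != DELAY_COMBINATION:
        raise ValueError(
            "the delay parameter is fit only on the reference combination by default; "
            "set allow_delay_any_variant to override"
        )
    cache = input_cache if input_cache is not None else {}
    results: dict[tuple[str, str], FlowResult] = {}
    for scan in study.scans:
        key = (study.subject_id, scan.condition, scan.repeat, variant.roi, variant.soc)
        if key in cache:
            input_tac, lv_fit, global_dv_cached = cache[key]
        else:
            input_tac = scan.blood_roi if variant.roi == "blood" else scan.uptake_roi
            lv_fit = None
            if variant.soc:
                input_tac, lv_fit = soc_input(input_tac, scan.whole_lv, config.soc)
            global_dv_cached = estimate_global_dv(scan.polar, input_tac, config)
            cache[key] = (input_tac, lv_fit, global_dv_cached)
        global_dv = global_dv_cached if variant.dv == "global" else None
        input_curve = tac_to_curve(input_tac, step=config.curve_step)
        polar = scan.polar
        fits = [
            fit_sector(
                polar.sector_tac(i),
                input_tac,
                scan.rv if variant.rbc else None,
                variant,
                global_dv,
                septal=bool(polar.septal[i]),
                config=config,
                sector_id=i,
                input_curve=input_curve,
            )
            for i in range(polar.n_sectors)
        ]
        mbf = np.array([mbf_of_k1(f.params.k1, variant.extraction) for f in fits])
        territory_mbf = {
            t: float(mbf[polar.territory == t].mean()) for t in TERRITORIES
        }
        results[(scan.condition, scan.repeat)] = FlowResult(
            scan.condition, scan.repeat, mbf, territory_mbf, fits, global_dv, lv_fit
        )
    return StudyFlows(study.subject_id, variant, results)


# ---------------------------------------------------------------------------
# extraction calibration
# ---------------------------------------------------------------------------


def calibrate_extraction(reference_mbf, k1) -> ExtractionFunction:
    """Fit (a, b) of the extraction model to paired (MBF, K1) values.

    Minimizes the mean squared error of K1 = (1 - a exp(-b/MBF)) MBF over the
    pairs; this is how a spillover-corrected method is recalibrated against a
    reference method's flow values.
    """
    mbf = np.asarray(reference_mbf, dtype=float)
    k1 = np.asarray(k1, dtype=float)
    if mbf.shape != k1.shape or mbf.size < 10:
        raise ValueError("need >= 10 paired values")
    if np.any(mbf <= 0) or np.any(k1 <= 0):
        raise ValueError("MBF and K1 values must be positive")
    if np.ptp(mbf) < 1e-9 * mbf.mean():
        raise ValueError("MBF values have no spread; (a, b) are not identifiable")

    def resid(theta):
        a, b = theta
        return (1.0 - a * np.exp(-b / mbf)) * mbf - k1

    sol = least_squares(resid, x0=[0.7, 0.5], bounds=([1e-6, 1e-6], [1 - 1e-6, 50.0]))
    return ExtractionFunction(a=float(sol.x[0]), b=float(sol.x[1]))


def nonconvergence_rate(fits: list[SectorFit], parameter: str = "any") -> float:
    """Fraction of sector fits that hit a bound on ``parameter``.

    With ``parameter='any'``: fraction with any boundary hit, optimizer
    failure or degenerate data — the operational nonconvergence definition.
    """
    if not fits:
        raise ValueError("empty fit list")
    if parameter == "any":
        bad = [not f.converged for f in fits]
    else:
        bad = [f.hit(parameter) for f in fits]
    return float(np.mean(bad))
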