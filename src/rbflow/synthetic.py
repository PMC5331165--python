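"""Synthetic test-retest rubidium PET studies with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* an arterial bolus shaped like a gamma-variate (constant-activity infusion
  over ~30 s) with a recirculation plateau so late frames keep blood
  activity;
* a right-ventricular input peaking ~10 s before the LV blood peak, with a
  higher first-pass amplitude (venous side of the lungs);
* per-sector myocardial tissue responses from the one-tissue-compartment
  model, with smooth spatial flow variation across a 496-sector polar map;
* mutual contamination of the sampled signals: sector TACs mix tissue with
  LV (and septally, RV) blood through fractional blood volumes, while the
  blood-ROI and uptake-ROI TACs are beta-mixtures of pure blood and
  whole-LV tissue;
* Gaussian frame noise whose variance follows decay-corrected count
  statistics (proportional to activity x exp(lambda t) / frame duration);
* paired test-retest acquisitions at rest and under stress flows, with
  physiologic jitter between repeats and rate-pressure products correlated
  with flow.

Ground truth (per-sector kinetic parameters, true pure-blood input, true
territory flows) is retained so every downstream stage can be checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .fitting import Scan, Study
from .model import (
    TAC,
    ContinuousCurve,
    EXTRACTION_PRESETS,
    PolarMap,
    TimeGrid,
    default_grid,
    frame_average,
    k1_of_mbf,
    KineticParams,
    tissue_curve,
)
from .qa import gamma_variate

__all__ = [
    "SyntheticStudyConfig",
    "PolarTruth",
    "SyntheticStudy",
    "make_input_curves",
    "make_polar_truth",
    "make_scan",
    "make_study",
    "make_cohort",
]

#: 82Rb physical decay constant (half-life 76.4 s).
RB82_LAMBDA = math.log(2.0) / 76.4


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study conditions for the generator.

    Flow defaults follow the clinical scale of a rest/dipyridamole-stress
    rubidium protocol (rest ~0.9, stress ~2.1 mL/min/g); beta and blood
    volume fractions sit inside the ranges reported for image-derived ROIs.
    ``noise`` is the relative standard deviation at the peak frame of a TAC;
    other frames scale by decay-corrected count statistics.
    """

    rest_mbf: dict = field(
        default_factory=lambda: {"LAD": 0.95, "LCX": 0.85, "RCA": 0.90}
    )
    stress_mbf: dict = field(
        default_factory=lambda: {"LAD": 2.20, "LCX": 2.00, "RCA": 2.10}
    )
    dv: float = 0.9  # mL/g
    fbv_mean: float = 0.28
    rvbv_septal: float = 0.10
    beta_blood_roi: float = 0.90
    beta_uptake_roi: float = 0.80
    #: scan-to-scan SD of the pure-blood fractions: ROI placement and partial
    #: volume vary between repeats, so the sampled blood purity is not a
    #: fixed property of the subject (clinical beta estimates vary by ~0.03
    #: between same-day repeats)
    beta_scan_jitter_sd: float = 0.03
    transport_delay_s: float = 1.5
    truth_extraction: str = "soc_on"  # extraction generating K1 from true MBF

    # bolus shape (peak-normalized gamma-variate) + recirculation
    bolus_amplitude: float = 100.0  # kBq/mL at the peak
    bolus_t0: float = 5.0
    bolus_alpha: float = 3.0
    bolus_tau: float = 8.0
    recirc_fraction: float = 0.15  # late plateau as a fraction of the peak
    recirc_tau: float = 40.0
    bolus_jitter_cv: float = 0.03  # per-scan injection variability
    rv_peak_lead: float = 10.0  # s before the LV blood peak
    rv_amplitude_factor: float = 1.2

    # noise model
    noise: float = 0.02
    noise_ref_duration_s: float = 10.0  # frame length at which `noise` is the peak rel. SD
    sector_noise_factor: float = 2.0
    blood_roi_noise_factor: float = 1.0
    uptake_roi_noise_factor: float = 0.7
    whole_lv_noise_factor: float = 0.5
    rv_noise_factor: float = 1.0
    decay_lambda: float = RB82_LAMBDA

    # cohort structure
    n_sectors: int = 496
    flow_spatial_cv: float = 0.03  # smooth within-territory variation, <= 5%
    jitter_cv: float = 0.05  # test-retest physiologic jitter on flows
    between_subject_cv: float = 0.15
    defect_depth: float = 0.0  # fractional flow reduction of the defect patch
    defect_extent: float = 0.1  # fraction of sectors covered when enabled

    # hemodynamics
    rpp_rest: float = 8240.0
    rpp_stress: float = 10638.0
    rpp_noise_cv: float = 0.05

    step: float = 0.1  # fine-curve step, s
    grid: TimeGrid = field(default_factory=default_grid)


@dataclass
class PolarTruth:
    """Ground-truth spatial fields over the polar map."""

    territory: np.ndarray
    septal: np.ndarray
    flow_multiplier: np.ndarray  # per-sector relative flow (mean ~1)
    fbv: np.ndarray
    rvbv: np.ndarray

    @property
    def n_sectors(self) -> int:
        return self.territory.size


@dataclass
class SyntheticStudy(Study):
    """A generated study plus everything needed to check recovery."""

    truth: PolarTruth
    flows: dict  # (condition, repeat) -> {territory: true MBF}
    true_inputs: dict  # (condition, repeat) -> true pure-blood TAC
    config: "SyntheticStudyConfig"
    true_betas: dict | None = None  # (condition, repeat) -> (beta_blood, beta_uptake)

    def true_territory_mbf(self, condition: str, repeat: str) -> dict:
        """Sector-averaged true MBF per territory (comparable to fitted means)."""
        base = self.flows[(condition, repeat)]
        out = {}
        for t in base:
            m = self.truth.territory == t
            out[t] = float(base[t] * self.truth.flow_multiplier[m].mean())
        return out

    def true_params(self, condition: str, repeat: str) -> list[KineticParams]:
        ext = EXTRACTION_PRESETS[self.config.truth_extraction]
        base = self.flows[(condition, repeat)]
        params = []
        for i in range(self.truth.n_sectors):
            mbf = base[self.truth.territory[i]] * self.truth.flow_multiplier[i]
            params.append(
                KineticParams(
                    k1=k1_of_mbf(mbf, ext),
                    dv=self.config.dv,
                    fbv=self.truth.fbv[i],
                    rvbv=self.truth.rvbv[i],
                    delay=self.config.transport_delay_s,
                )
            )
        return params


# ---------------------------------------------------------------------------
# input curves
# ---------------------------------------------------------------------------


def _bolus_with_recirc(t, amp, t0, alpha, tau, frac, recirc_tau):
    first_pass = gamma_variate(t, amp, t0, alpha, tau)
    recirc = frac * amp * -np.expm1(-np.maximum(t - t0, 0.0) / recirc_tau)
    return first_pass + recirc


def make_input_curves(
    config: SyntheticStudyConfig, seed: int | None = None
) -> tuple[ContinuousCurve, ContinuousCurve]:
    """True pure arterial (LV) and right-ventricular input curves.

    A seed applies the per-scan injection jitter to the bolus parameters;
    ``seed=None`` returns the nominal curves.
    """
    amp, t0, alpha, tau = (
        config.bolus_amplitude,
        config.bolus_t0,
        config.bolus_alpha,
        config.bolus_tau,
    )
    if seed is not None and config.bolus_jitter_cv > 0:
        rng = np.random.default_rng(seed)
        j = 1.0 + config.bolus_jitter_cv * rng.standard_normal(4)
        amp, t0, alpha, tau = amp * j[0], max(t0 * j[1], 0.5), alpha * j[2], tau * j[3]

    duration = config.grid.end
    t = np.arange(int(round(duration / config.step)) + 1) * config.step
    cb = _bolus_with_recirc(t, amp, t0, alpha, tau, config.recirc_fraction, config.recirc_tau)

    # RV bolus: same shape family, peak led by rv_peak_lead, higher amplitude
    peak_time = t0 + alpha * tau
    rv_peak = max(peak_time - config.rv_peak_lead, 1.0)
    rv_t0 = max(t0 - config.rv_peak_lead, 0.0)
    rv_tau = (rv_peak - rv_t0) / alpha
    crv = _bolus_with_recirc(
        t,
        config.rv_amplitude_factor * amp,
        rv_t0,
        alpha,
        rv_tau,
        config.recirc_fraction / config.rv_amplitude_factor,
        config.recirc_tau,
    )
    return ContinuousCurve(config.step, cb), ContinuousCurve(config.step, crv)


# ---------------------------------------------------------------------------
# polar-map ground truth
# ---------------------------------------------------------------------------


def make_polar_truth(config: SyntheticStudyConfig, seed: int = 0) -> PolarTruth:
    """Territory wedges, septal half, and smooth spatial parameter fields.

    Sectors are laid out on the angular coordinate of the bull's-eye: the
    LAD wedge spans [0, 150) degrees, LCX [150, 255), RCA [255, 360); the
    septal half is [90, 270).  Flow varies smoothly (low-order harmonics)
    with a small coefficient of variation; an optional defect patch reduces
    flow locally.
    """
    n = config.n_sectors
    rng = np.random.default_rng(seed)
    theta = 2.0 * np.pi * np.arange(n) / n
    deg = np.degrees(theta)
    territory = np.where(deg < 150.0, "LAD", np.where(deg < 255.0, "LCX", "RCA"))
    septal = (deg >= 90.0) & (deg < 270.0)

    phases = rng.uniform(0, 2 * np.pi, size=3)
    raw = np.sin(theta + phases[0]) + 0.5 * np.sin(2 * theta + phases[1])
    mult = 1.0 + config.flow_spatial_cv * raw / np.std(raw)
    if config.defect_depth > 0:
        width = max(int(round(config.defect_extent * n)), 1)
        start = int(rng.integers(0, n))
        idx = (np.arange(width) + start) % n
        mult[idx] *= 1.0 - config.defect_depth

    fbv = config.fbv_mean * (1.0 + 0.1 * np.sin(theta + phases[2]))
    fbv = np.clip(fbv, 0.0, 0.6)
    rvbv = np.where(septal, config.rvbv_septal, 0.0)
    return PolarTruth(territory, septal, mult, fbv, rvbv)


# ---------------------------------------------------------------------------
# one scan
# ---------------------------------------------------------------------------


def _count_noise(
    values: np.ndarray, grid: TimeGrid, level: float, lam: float, rng, ref_duration: float = 10.0
) -> np.ndarray:
    """Gaussian noise with variance ~ value * exp(lambda t) / duration.

    ``level`` is the relative standard deviation the peak frame would have at
    ``ref_duration`` seconds; shorter frames are correspondingly noisier, so
    regridding keeps the noise matched per unit time.
    """
    if level <= 0:
        return np.zeros_like(values)
    relvar = np.maximum(values, 0.0) * np.exp(lam * grid.frame_mid) / grid.frame_duration
    ipk = int(np.argmax(values))
    ref = values[ipk] * np.exp(lam * grid.frame_mid[ipk]) / ref_duration
    if ref <= 0:
        ref = 1.0
    sd = level * values[ipk] * np.sqrt(relvar / ref)
    return sd * rng.standard_normal(values.size)


def make_scan(
    config: SyntheticStudyConfig,
    truth: PolarTruth,
    flows: dict,
    condition: str,
    repeat: str,
    seed: int,
) -> tuple[Scan, TAC]:
    """Forward-simulate one dynamic acquisition.

    Returns the Scan (sampled, noisy TACs), the true pure-blood TAC on the
    frame grid, and the realized (beta_blood, beta_uptake) pair.  Two calls
    with the same arguments are bit-identical.
    """
    rng = np.random.default_rng(seed)
    grid = config.grid
    ext = EXTRACTION_PRESETS[config.truth_extraction]

    cb_curve, crv_curve = make_input_curves(config, seed=seed)
    cb_frames = frame_average(cb_curve, grid).values
    crv_frames = frame_average(crv_curve, grid).values

    n = truth.n_sectors
    tissue_frames = np.empty((n, grid.n_frames))
    for i in range(n):
        mbf = flows[truth.territory[i]] * truth.flow_multiplier[i]
        params = KineticParams(
            k1=k1_of_mbf(mbf, ext), dv=config.dv, delay=config.transport_delay_s
        )
        tissue_frames[i] = frame_average(tissue_curve(params, cb_curve), grid).values

    # sector myocardium signals: LV (and septal RV) blood mixed into tissue
    fbv = truth.fbv[:, None]
    rvbv = truth.rvbv[:, None]
    sector_vals = fbv * cb_frames + rvbv * crv_frames + (1.0 - fbv - rvbv) * tissue_frames

    # whole-LV average tissue (uptake-weighted) and the contaminated samples
    uptake_w = np.maximum(tissue_frames[:, grid.frame_start >= 120.0].mean(axis=1), 1e-12)
    ct_whole = (uptake_w[:, None] * tissue_frames).sum(axis=0) / uptake_w.sum()
    fbv_lv = float(truth.fbv.mean())
    whole_lv = fbv_lv * cb_frames + (1.0 - fbv_lv) * ct_whole
    sd = config.beta_scan_jitter_sd
    beta_b = float(np.clip(config.beta_blood_roi + sd * rng.standard_normal(), 0.55, 0.99))
    beta_u = float(np.clip(config.beta_uptake_roi + sd * rng.standard_normal(), 0.55, 0.99))
    blood_roi = beta_b * cb_frames + (1.0 - beta_b) * ct_whole
    uptake_roi = beta_u * cb_frames + (1.0 - beta_u) * ct_whole

    lam = config.decay_lambda
    lvl = config.noise
    ref = config.noise_ref_duration_s
    sector_vals = sector_vals + np.stack(
        [
            _count_noise(sector_vals[i], grid, lvl * config.sector_noise_factor, lam, rng, ref)
            for i in range(n)
        ]
    )
    blood_roi = blood_roi + _count_noise(blood_roi, grid, lvl * config.blood_roi_noise_factor, lam, rng, ref)
    uptake_roi = uptake_roi + _count_noise(uptake_roi, grid, lvl * config.uptake_roi_noise_factor, lam, rng, ref)
    whole_lv = whole_lv + _count_noise(whole_lv, grid, lvl * config.whole_lv_noise_factor, lam, rng, ref)
    rv_tac = crv_frames + _count_noise(crv_frames, grid, lvl * config.rv_noise_factor, lam, rng, ref)

    # RPP correlated with achieved flow relative to the configured base
    base_rpp = config.rpp_rest if condition == "rest" else config.rpp_stress
    base_flow = np.mean(list((config.rest_mbf if condition == "rest" else config.stress_mbf).values()))
    flow_ratio = np.mean(list(flows.values())) / base_flow
    rpp = base_rpp * flow_ratio * (1.0 + config.rpp_noise_cv * rng.standard_normal())

    polar = PolarMap(grid, sector_vals, truth.territory, truth.septal)
    scan = Scan(
        condition=condition,
        repeat=repeat,
        blood_roi=TAC(grid, blood_roi),
        uptake_roi=TAC(grid, uptake_roi),
        whole_lv=TAC(grid, whole_lv),
        rv=TAC(grid, rv_tac),
        polar=polar,
        rpp=float(rpp),
    )
    return scan, TAC(grid, cb_frames), (beta_b, beta_u)


# ---------------------------------------------------------------------------
# studies and cohorts
# ---------------------------------------------------------------------------


def make_study(config: SyntheticStudyConfig, seed: int = 0, subject_id: str = "S01") -> SyntheticStudy:
    """Four scans (rest/stress x test/retest) with physiologic jitter."""
    rng = np.random.default_rng(seed)
    truth = make_polar_truth(config, seed=int(rng.integers(2**31)))

    scans, flows, true_inputs, betas = [], {}, {}, {}
    for condition, base in (("rest", config.rest_mbf), ("stress", config.stress_mbf)):
        for repeat in ("test", "retest"):
            jit = {
                t: float(v * max(1.0 + config.jitter_cv * rng.standard_normal(), 0.1))
                for t, v in base.items()
            }
            scan, true_cb, scan_betas = make_scan(
                config, truth, jit, condition, repeat, seed=int(rng.integers(2**31))
            )
            scans.append(scan)
            flows[(condition, repeat)] = jit
            true_inputs[(condition, repeat)] = true_cb
            betas[(condition, repeat)] = scan_betas
    return SyntheticStudy(subject_id, scans, truth, flows, true_inputs, config, betas)


def make_cohort(n_subjects: int, config: SyntheticStudyConfig, seed: int = 0) -> list[SyntheticStudy]:
    """Independent subjects with between-subject flow variation."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    studies = []
    for i in range(n_subjects):
        scale_rest = max(1.0 + config.between_subject_cv * rng.standard_normal(), 0.2)
        scale_stress = max(1.0 + config.between_subject_cv * rng.standard_normal(), 0.2)
        cfg = dc_replace(
            config,
            rest_mbf={t: v * scale_rest for t, v in config.rest_mbf.items()},
            stress_mbf={t: v * scale_stress for t, v in config.stress_mbf.items()},
        )
        studies.append(
            make_study(cfg, seed=int(rng.integers(2**31)), subject_id=f"S{i + 1:02d}")
        )
    return studies
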