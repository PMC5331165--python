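"""Core kinetic model for dynamic cardiac PET time-activity data.

The forward model is the one-tissue-compartment model widely used for
rubidium-82 myocardial blood flow quantification: tracer enters the
myocardium from arterial blood at uptake rate ``K1`` (mL/min/g) and washes
out at rate ``k2`` (1/min), so the tissue concentration is the convolution
of the arterial input with ``K1 * exp(-k2 * t)``.  The image-sampled
myocardium signal additionally contains a fractional-blood-volume mixing
term that models partial-volume losses and blood-to-tissue spillover.

Time grids are in seconds (PET frame schedules); kinetic rates are per
minute.  The unit conversion happens inside :func:`tissue_response` only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.signal import lfilter

__all__ = [
    "ParameterError",
    "GridMismatchError",
    "InputDomainError",
    "TimeGrid",
    "TAC",
    "ContinuousCurve",
    "ExtractionFunction",
    "LORTIE",
    "SOC_ON_EXTRACTION",
    "EXTRACTION_PRESETS",
    "KineticParams",
    "ModelVariant",
    "REFERENCE_VARIANT",
    "PolarMap",
    "default_grid",
    "fine_grid",
    "tissue_response",
    "tissue_curve",
    "frame_average",
    "rebin",
    "tac_to_curve",
    "mix_lv",
    "mix_lv_rv",
    "k1_of_mbf",
    "mbf_of_k1",
    "variant_catalog",
]


class ParameterError(ValueError):
    """A kinetic or mixing parameter is outside its physical domain."""


class GridMismatchError(ValueError):
    """Two TACs that must share a frame schedule do not."""


class InputDomainError(ValueError):
    """The requested output extends beyond the supplied input curve."""


# ---------------------------------------------------------------------------
# time grids and curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """A contiguous dynamic-PET frame schedule, in seconds."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.shape != start.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if start.size == 0:
            raise ValueError("empty frame schedule")
        if start[0] < 0:
            raise ValueError("first frame start must be >= 0")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def end(self) -> float:
        return float(self.frame_end[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeGrid):
            return NotImplemented
        return (
            self.frame_start.shape == other.frame_start.shape
            and np.allclose(self.frame_start, other.frame_start)
            and np.allclose(self.frame_duration, other.frame_duration)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.frame_start.tobytes(), self.frame_duration.tobytes()))


def default_grid() -> TimeGrid:
    """The 14-frame clinical schedule: 9 x 10 s, 3 x 30 s, 1 x 60 s, 1 x 120 s."""
    dur = np.array([10.0] * 9 + [30.0] * 3 + [60.0, 120.0])
    start = np.concatenate(([0.0], np.cumsum(dur)[:-1]))
    return TimeGrid(start, dur)


def fine_grid(frame_s: float = 1.0, total_s: float = 360.0) -> TimeGrid:
    """A uniform grid of ``frame_s``-second frames covering ``total_s`` seconds."""
    n = int(round(total_s / frame_s))
    dur = np.full(n, float(frame_s))
    start = np.arange(n) * float(frame_s)
    return TimeGrid(start, dur)


@dataclass(frozen=True)
class TAC:
    """A framed time-activity curve; values are frame time-averages (kBq/mL)."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.grid.n_frames,):
            raise ValueError(
                f"TAC has {v.size} values for a {self.grid.n_frames}-frame grid"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("TAC values must be finite")

    def with_values(self, values: np.ndarray) -> "TAC":
        return TAC(self.grid, values)


@dataclass(frozen=True)
class ContinuousCurve:
    """Uniform fine sampling of a concentration function on [0, T].

    Simulation/convolution substrate: values[i] = C(i * step).
    """

    step: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.step <= 0:
            raise ValueError("step must be positive")
        if v.ndim != 1 or v.size < 2:
            raise ValueError("curve needs at least two samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.values.size) * self.step

    @property
    def duration(self) -> float:
        return (self.values.size - 1) * self.step

    @classmethod
    def from_function(
        cls, f: Callable[[np.ndarray], np.ndarray], duration: float, step: float = 0.1
    ) -> "ContinuousCurve":
        t = np.arange(int(round(duration / step)) + 1) * step
        return cls(step, np.asarray(f(t), dtype=float))


def frame_average(curve: ContinuousCurve, grid: TimeGrid) -> TAC:
    """Average a fine curve over each frame (trapezoidal integral / duration)."""
    if grid.end > curve.duration + 1e-9:
        raise InputDomainError(
            f"grid ends at {grid.end:.1f} s but curve covers only {curve.duration:.1f} s"
        )
    t = curve.t
    cum = np.concatenate(([0.0], cumulative_trapezoid(curve.values, t)))
    lo = np.interp(grid.frame_start, t, cum)
    hi = np.interp(grid.frame_end, t, cum)
    return TAC(grid, (hi - lo) / grid.frame_duration)


_KNOT_MATRIX_CACHE: dict = {}


def _knot_matrix(grid: TimeGrid, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Map from knot values (at frame midpoints) to frame averages.

    The lifted curve is piecewise linear through the knots, held flat before
    the first and after the last midpoint; column k of the matrix is the
    frame-average response to a unit value at knot k.
    """
    key = (hash(grid), step)
    if key in _KNOT_MATRIX_CACHE:
        return _KNOT_MATRIX_CACHE[key]
    mids = grid.frame_mid
    t = np.arange(int(round(grid.end / step)) + 1) * step
    n = grid.n_frames
    m = np.empty((n, n))
    for k in range(n):
        unit = np.zeros(n)
        unit[k] = 1.0
        curve = ContinuousCurve(step, np.interp(t, mids, unit))
        m[:, k] = frame_average(curve, grid).values
    _KNOT_MATRIX_CACHE[key] = (m, t)
    return m, t


def rebin(tac: TAC, target: TimeGrid) -> TAC:
    """Aggregate a finely framed TAC onto a coarser schedule.

    Every target frame must be an exact union of source frames (as when
    list-mode data are rebinned); values combine as duration-weighted means,
    so noise aggregates the way counts do.
    """
    src = tac.grid
    out = np.empty(target.n_frames)
    for j in range(target.n_frames):
        m = (src.frame_start >= target.frame_start[j] - 1e-9) & (
            src.frame_end <= target.frame_end[j] + 1e-9
        )
        covered = src.frame_duration[m].sum()
        if abs(covered - target.frame_duration[j]) > 1e-6:
            raise GridMismatchError(
                f"target frame {j} is not an exact union of source frames"
            )
        out[j] = np.sum(tac.values[m] * src.frame_duration[m]) / target.frame_duration[j]
    return TAC(target, out)


def tac_to_curve(tac: TAC, step: float = 0.1) -> ContinuousCurve:
    """Lift a framed TAC to a fine curve, conserving the frame averages.

    The curve is piecewise linear through knots at the frame midpoints (flat
    beyond the first/last midpoint); the knot values are solved so that the
    curve's frame time-averages reproduce the TAC exactly.  This keeps the
    convolution model consistent with how PET frames aggregate activity,
    which matters for the sharp first-pass frames.
    """
    m, t = _knot_matrix(tac.grid, step)
    knots = np.linalg.solve(m, tac.values)
    # concentrations are nonnegative; the exact solve can ring slightly below
    # zero around the bolus onset, which would leak into the convolution
    vals = np.maximum(np.interp(t, tac.grid.frame_mid, knots), 0.0)
    return ContinuousCurve(step, vals)


# ---------------------------------------------------------------------------
# extraction functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtractionFunction:
    """Flow-dependent extraction: K1 = (1 - a * exp(-b / MBF)) * MBF.

    ``a`` is unitless (1 - a is the high-flow extraction plateau); ``b`` is in
    mL/min/g.  Strictly increasing in MBF, with K1 <= MBF everywhere.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a < 1.0):
            raise ParameterError(f"extraction coefficient a must be in (0, 1), got {self.a}")
        if self.b <= 0:
            raise ParameterError(f"extraction coefficient b must be positive, got {self.b}")


#: Lortie et al. rubidium extraction, calibrated against 13N-ammonia flows.
LORTIE = ExtractionFunction(a=0.77, b=0.63)

#: Extraction recalibrated for the spillover-corrected (pure-blood input) model.
SOC_ON_EXTRACTION = ExtractionFunction(a=0.76, b=0.40)

EXTRACTION_PRESETS = {"lortie": LORTIE, "soc_on": SOC_ON_EXTRACTION}


def k1_of_mbf(mbf, extraction: ExtractionFunction = LORTIE):
    """Convert flow to uptake rate through the extraction function.

    Vectorized over ``mbf``; K1(0) = 0 by continuity.
    """
    mbf = np.asarray(mbf, dtype=float)
    if np.any(mbf < 0):
        raise ParameterError("MBF must be nonnegative")
    with np.errstate(divide="ignore"):
        k1 = np.where(mbf > 0, (1.0 - extraction.a * np.exp(-extraction.b / np.maximum(mbf, 1e-300))) * mbf, 0.0)
    return float(k1) if k1.ndim == 0 else k1


def mbf_of_k1(k1: float, extraction: ExtractionFunction = LORTIE, rtol: float = 1e-8) -> float:
    """Invert the extraction function by monotone root-finding."""
    if k1 < 0:
        raise ParameterError("K1 must be nonnegative")
    if k1 == 0:
        return 0.0
    # K1 <= MBF, and K1 >= (1 - a) * MBF, so the root lies in [k1, k1 / (1 - a)].
    lo, hi = k1, k1 / (1.0 - extraction.a) + 1e-12
    return float(brentq(lambda m: k1_of_mbf(m, extraction) - k1, lo, hi, rtol=rtol))


# ---------------------------------------------------------------------------
# kinetic parameters and model variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParams:
    """One sector's kinetic and mixing parameters.

    ``k2 = K1 / DV`` ties washout to the distribution volume.  ``fbv`` is the
    LV blood fraction in the two-component mixing model; when right-ventricle
    spillover is modeled, ``lvbv``/``rvbv`` replace it (``fbv`` then mirrors
    ``lvbv``).  ``beta`` is the pure-blood fraction of the sampled blood TAC
    and only applies to whole-LV spillover fits.  ``delay`` is the arterial
    transport delay in seconds.
    """

    k1: float
    dv: float
    fbv: float = 0.0
    rvbv: float = 0.0
    beta: float = 1.0
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ParameterError("K1 must be nonnegative")
        if self.dv <= 0:
            raise ParameterError("DV must be positive")
        if not (0.0 <= self.fbv <= 1.0):
            raise ParameterError("FBV must be in [0, 1]")
        if self.rvbv < 0 or self.fbv + self.rvbv > 1.0 + 1e-12:
            raise ParameterError("require RVBV >= 0 and LVBV + RVBV <= 1")
        if not (0.0 < self.beta <= 1.0):
            raise ParameterError("beta must be in (0, 1]")
        if not (0.0 <= self.delay <= 10.0):
            raise ParameterError("delay must be in [0, 10] s")

    @property
    def k2(self) -> float:
        """Washout rate in 1/min."""
        return self.k1 / self.dv

    @property
    def lvbv(self) -> float:
        return self.fbv


@dataclass(frozen=True, order=True)
class ModelVariant:
    """One of the 2^5 = 32 analysis-method combinations.

    soc:   dual spillover correction of the arterial input (on/off)
    rbc:   right-ventricle blood spillover term in septal sectors (on/off)
    roi:   arterial input sampling region ('blood' = atrial blood pool,
           'uptake' = cavity cylinders from the uptake image)
    dv:    distribution volume 'global' (fit once on the normal-uptake
           region, then fixed) or 'regional' (free per sector)
    delay: arterial transport delay parameter (on/off)
    """

    soc: bool
    rbc: bool
    roi: str
    dv: str
    delay: bool

    def __post_init__(self) -> None:
        if self.roi not in ("blood", "uptake"):
            raise ValueError(f"roi must be 'blood' or 'uptake', got {self.roi!r}")
        if self.dv not in ("global", "regional"):
            raise ValueError(f"dv must be 'global' or 'regional', got {self.dv!r}")

    @property
    def label(self) -> str:
        onoff = lambda b: "On" if b else "Off"
        return (
            f"SOC-{onoff(self.soc)}/RBC-{onoff(self.rbc)}/"
            f"{self.roi.capitalize()}-ROI/{self.dv.capitalize()}-DV/"
            f"Delay-{onoff(self.delay)}"
        )

    @property
    def key(self) -> str:
        """Compact machine id, e.g. 'soc1_rbc0_blood_global_delay0'."""
        return (
            f"soc{int(self.soc)}_rbc{int(self.rbc)}_{self.roi}_{self.dv}_"
            f"delay{int(self.delay)}"
        )

    @property
    def extraction(self) -> ExtractionFunction:
        return SOC_ON_EXTRACTION if self.soc else LORTIE

    @classmethod
    def parse(cls, text: str) -> "ModelVariant":
        """Parse 'soc=on,rbc=off,roi=blood,dv=global,delay=off'."""
        fields = dict(
            item.strip().split("=", 1) for item in text.split(",") if item.strip()
        )
        onoff = {"on": True, "off": False}
        try:
            return cls(
                soc=onoff[fields["soc"].lower()],
                rbc=onoff[fields["rbc"].lower()],
                roi=fields["roi"].lower(),
                dv=fields["dv"].lower(),
                delay=onoff[fields["delay"].lower()],
            )
        except KeyError as exc:
            raise ValueError(f"bad variant string {text!r}: missing/invalid {exc}") from exc


#: Blood-ROI, SOC-On, RBC-Off, Global-DV, Delay-Off — the most repeatable
#: combination, used as the comparison reference.
REFERENCE_VARIANT = ModelVariant(soc=True, rbc=False, roi="blood", dv="global", delay=False)


def variant_catalog(allow_delay: bool = True) -> list[ModelVariant]:
    """Full factorial over the five switches, in fixed lexicographic order.

    32 variants with the delay switch free, 16 with delay pinned off.
    """
    delays = (False, True) if allow_delay else (False,)
    return [
        ModelVariant(soc=soc, rbc=rbc, roi=roi, dv=dv, delay=delay)
        for soc in (False, True)
        for rbc in (False, True)
        for roi in ("blood", "uptake")
        for dv in ("global", "regional")
        for delay in delays
    ]


# ---------------------------------------------------------------------------
# polar map
# ---------------------------------------------------------------------------

TERRITORIES = ("LAD", "LCX", "RCA")


@dataclass
class PolarMap:
    """Bull's-eye sampling of the LV myocardium into sectors.

    ``values`` is (n_sectors, n_frames); ``territory`` assigns each sector to
    a coronary territory (LAD/LCX/RCA); ``septal`` flags the septal half where
    right-ventricular blood spillover is expected; ``uptake`` is the
    late-frame mean used for normal-region selection.  The default clinical
    layout has 496 sectors, half of them septal.
    """

    grid: TimeGrid
    values: np.ndarray
    territory: np.ndarray
    septal: np.ndarray
    uptake: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.territory = np.asarray(self.territory)
        self.septal = np.asarray(self.septal, dtype=bool)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n_frames:
            raise ValueError("values must be (n_sectors, n_frames)")
        if self.territory.shape != (n,) or self.septal.shape != (n,):
            raise ValueError("territory and septal must have one entry per sector")
        unknown = set(np.unique(self.territory)) - set(TERRITORIES)
        if unknown:
            raise ValueError(f"unknown territories: {sorted(unknown)}")
        if self.uptake is None:
            # late-uptake mean: frames starting at or after 120 s
            late = self.grid.frame_start >= 120.0
            self.uptake = self.values[:, late].mean(axis=1)
        self.uptake = np.asarray(self.uptake, dtype=float)
        if self.uptake.shape != (n,):
            raise ValueError("uptake must have one entry per sector")

    @property
    def n_sectors(self) -> int:
        return self.values.shape[0]

    def sector_tac(self, i: int) -> TAC:
        return TAC(self.grid, self.values[i])


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _exp_conv(values: np.ndarray, step: float, k_per_s: float) -> np.ndarray:
    """y(t) = int_0^t exp(-k (t-s)) f(s) ds for piecewise-linear f, exactly.

    Uses the one-step recursion y[i] = a y[i-1] + u[i] with the segment
    integral in closed form, evaluated by a first-order IIR filter.
    """
    kdt = k_per_s * step
    a = np.exp(-kdt)
    one_minus_a = -np.expm1(-kdt)
    c0 = one_minus_a / k_per_s  # weight of the segment's left endpoint
    cm = one_minus_a / k_per_s - (one_minus_a - kdt * a) / (k_per_s * k_per_s * step)
    left, right = values[:-1], values[1:]
    u = np.empty_like(values)
    u[0] = 0.0
    u[1:] = c0 * left + cm * (right - left)
    return lfilter([1.0], [1.0, -a], u)


def tissue_curve(params: KineticParams, blood: ContinuousCurve) -> ContinuousCurve:
    """Fine-grid myocardial tissue response to an arterial input.

    C_t(t) = K1 exp(-k2 (t - delay)) (*) C_blood(t), zero for t <= delay; the
    delay shifts the exponential kernel, with the input taken as zero before
    time zero.  K1 and k2 are per-minute; the curve grid is in seconds.
    """
    if params.k2 <= 0:
        raise ParameterError("k2 must be positive (K1 > 0 and DV > 0)")
    k_per_s = params.k2 / 60.0
    y = (params.k1 / 60.0) * _exp_conv(blood.values, blood.step, k_per_s)
    if params.delay > 0:
        t = blood.t
        y = np.interp(t - params.delay, t, y, left=0.0)
    return ContinuousCurve(blood.step, y)


def tissue_response(params: KineticParams, blood: ContinuousCurve, grid: TimeGrid) -> TAC:
    """Frame-averaged tissue TAC for the one-tissue-compartment model.

    The transport delay is applied by integrating the undelayed response
    over delay-shifted frame windows, which avoids resampling error at the
    tissue onset.
    """
    if params.k1 == 0:
        if grid.end > blood.duration + 1e-9:
            raise InputDomainError("grid extends beyond the blood curve")
        return TAC(grid, np.zeros(grid.n_frames))
    if grid.end > blood.duration + 1e-9:
        raise InputDomainError(
            f"grid ends at {grid.end:.1f} s but curve covers only {blood.duration:.1f} s"
        )
    undelayed = tissue_curve(replace(params, delay=0.0), blood)
    t = undelayed.t
    cum = np.concatenate(([0.0], cumulative_trapezoid(undelayed.values, t)))
    lo = np.interp(np.maximum(grid.frame_start - params.delay, 0.0), t, cum)
    hi = np.interp(np.maximum(grid.frame_end - params.delay, 0.0), t, cum)
    return TAC(grid, (hi - lo) / grid.frame_duration)


# ---------------------------------------------------------------------------
# signal mixing (partial volume / spillover)
# ---------------------------------------------------------------------------


def _require_same_grid(*tacs: TAC) -> None:
    g0 = tacs[0].grid
    for t in tacs[1:]:
        if t.grid != g0:
            raise GridMismatchError("TACs must share one frame schedule")


def mix_lv(tissue: TAC, blood: TAC, fbv: float) -> TAC:
    """Two-component mixing: FBV * blood + (1 - FBV) * tissue."""
    _require_same_grid(tissue, blood)
    if not (0.0 <= fbv <= 1.0):
        raise ParameterError(f"FBV must be in [0, 1], got {fbv}")
    return TAC(tissue.grid, fbv * blood.values + (1.0 - fbv) * tissue.values)


def mix_lv_rv(tissue: TAC, blood: TAC, rv: TAC, lvbv: float, rvbv: float) -> TAC:
    """Three-component mixing with right-ventricular blood spillover."""
    _require_same_grid(tissue, blood, rv)
    if lvbv < 0 or rvbv < 0:
        raise ParameterError("LVBV and RVBV must be nonnegative")
    if lvbv + rvbv > 1.0:
        raise ParameterError(f"LVBV + RVBV must not exceed 1, got {lvbv + rvbv}")
    mixed = lvbv * blood.values + rvbv * rv.values + (1.0 - lvbv - rvbv) * tissue.values
    return TAC(tissue.grid, mixed)
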