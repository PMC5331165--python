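# Methods

This note records the modelling and numerical choices behind `rbflow`: the
kinetic model and its variants, how the spillover correction is identified,
what the synthetic-data generator does and does not emulate, the statistics,
and the known limitations.

## Kinetic model and variants

The tissue model is the one-tissue-compartment model for ⁸²Rb,
`C_t = K1 · exp(−k2 (t − Δ)) ⊗ C_b`, with washout tied to the distribution
volume through `k2 = K1/DV`.  K1 and MBF are in mL/min/g, k2 in 1/min, time
grids in seconds; the 1/60 unit conversion lives inside `tissue_response`
only.  Frame values are *time averages* over the frame (integral divided by
duration), matching how reconstructed PET frames aggregate counts; the same
convention is used in simulation and in fitting.  The transport delay shifts
the exponential kernel, with the input taken as zero before time zero; it is
evaluated by integrating the undelayed response over delay-shifted frame
windows, which is exact up to edge interpolation and avoids resampling error
at the tissue onset.

The convolution itself is computed exactly for a piecewise-linear input on a
fine uniform grid (closed-form segment integrals chained through a
first-order recursion), so accuracy is limited by the input representation,
not the quadrature.  Against a 0.01 s brute-force discrete convolution the
frame values agree to better than 0.1% wherever the frame value exceeds
0.5% of the curve peak; smaller frames (the near-zero onset) are compared on
that absolute floor, since a ratio of two near-zero discretizations is not
informative.

Five binary switches define 2⁵ = 32 analysis variants: dual spillover
correction of the input (SOC), right-ventricular blood correction in septal
sectors (RBC), input ROI (atrial blood pool vs uptake-derived cavity
regions), global vs regional distribution volume, and transport delay.  The
comparison preset runs the 16 delay-off variants plus the single delay-on
combination of the reference method (17 rows); delay is fit in other
combinations only behind a configuration flag, because the delay parameter
is poorly identifiable at clinical frame durations (below).

Sector fits minimize frame-duration-weighted squared residuals with
`scipy.optimize.least_squares` under box bounds (K1 ∈ [0.01, 5] mL/min/g,
FBV ∈ [0, 1], RVBV ∈ [0, 0.5], DV ∈ [0.2, 5] mL/g, Δ ∈ [0, 10] s), from
fixed initial values (K1 = 0.5, FBV = 0.3, DV = 1.0, Δ = 2 s) with optional
seeded multistart.  A fit is *nonconverged* when the optimizer fails or any
estimate lands within 10⁻³ of its bound range — the operational definition
used for the delay nonconvergence accounting.  The global DV is estimated by
averaging the TACs of sectors above 75% of the maximum uptake into one
low-noise TAC and fitting the free model to it once.

Framed TACs are lifted to fine curves for convolution by a
frame-average-conserving piecewise-linear interpolation: knot values at the
frame midpoints are solved so that the lifted curve's frame means reproduce
the TAC exactly, then clipped at zero (concentrations are nonnegative and
the exact solve can ring slightly below zero at the bolus onset).  Plain
midpoint interpolation leaves a systematic error of about 0.5% of the peak
in the convolved model, which is larger than the spillover-fit information
content and was observed to bias that fit; the conserving lift removes most
of it.

## Identifying the spillover correction

Writing the sampled blood and whole-LV TACs as complementary mixtures of
pure blood `C_b` and pure tissue `C_t` (pure-blood fraction β, blood volume
fraction FBV) makes the unmixing algebraic.  A key structural fact, verified
numerically in this package: **β is not identifiable from the weighted data
term alone.**  For any candidate β, adjusted (K1, k2, FBV) reproduce the
whole-LV TAC essentially exactly, because the candidate input is a linear
mixture of two smooth curves and the single-exponential convolution family
is flexible enough to absorb the difference at 14 frames.  Identification
must come from physical constraints, and the fit therefore carries two
penalty families:

* negativity of the implied `C_b` and `C_t` frames (smooth, quadratic,
  weight 10× the mean squared signal), and
* a late-residual prior: pure arterial blood clears to its recirculation
  plateau, so the decay-weighted mean of `C_b` over the last 4 minutes is
  penalized (two-sided, same weight scale) away from `late_fraction` of its
  first-pass mean (frames starting before 60 s).  The default
  `late_fraction = 0.244` is the plateau-to-first-pass-mean ratio of the
  nominal bolus model (gamma-variate plus 15% recirculation plateau), i.e. a
  physiological calibration, not a fitted constant.  Both reference levels
  are multi-frame averages — the late mean weighted by
  `duration · exp(−λt)` (inverse variance under decay-corrected count
  statistics) — because single-frame references (e.g. the noisy peak) were
  found to dominate the β estimation variance.

With this design the whole-LV fit recovers (K1, k2, FBV, β) within 2% on
noise-free mixtures and β/FBV with median absolute errors of about
0.02/0.01 at 2% count noise.  The residual β noise (~0.02–0.03 SD) is an
information bound set by late-frame count noise in the blood ROI; it is the
main reason the spillover correction's repeatability advantage is modest in
simulation (below).

## Synthetic studies

The generator emulates the statistical structure the analysis assumes, with
defaults chosen as the study conditions:

* **Flows**: rest ≈ 0.9, stress ≈ 2.1 mL/min/g per territory (clinical
  rest/dipyridamole scale), smooth spatial variation with 3% CV, optional
  defect patch.  True K1 derives from MBF via the spillover-corrected
  extraction function, making the SOC-On analysis path
  calibration-consistent; SOC-Off paths carry the corresponding bias, which
  is why a separate extraction calibration exists at all.
* **Input**: gamma-variate bolus (peak 100 kBq/mL at ~29 s, consistent with
  a 30 s constant-activity infusion) plus a smoothly joined recirculation
  plateau at 15% of the peak; per-scan injection jitter of 3% CV on the
  bolus parameters.  The RV input peaks 10 s before the LV blood peak with
  1.2× amplitude.
* **Mixing**: sector TACs mix tissue with LV blood (FBV ≈ 0.28) and, in the
  septal half, RV blood (RVBV = 0.10); the blood-ROI and uptake-ROI TACs are
  β-mixtures of pure blood and whole-LV tissue with β = 0.90 and 0.80.  β
  jitters per scan with SD 0.03: ROI placement and partial volume vary
  between repeats, so sampled blood purity is not a fixed property of the
  subject — without this, contamination would be bit-identical between test
  and retest and would cancel from every difference, contradicting the
  premise that spillover degrades repeatability.
* **Noise**: Gaussian, variance ∝ value · e^{λt}/duration (decay-corrected
  count statistics, λ = ln2/76.4 s⁻¹), scaled so the peak frame of a 10 s
  schedule has 2% relative SD; sectors are 2× noisier, the uptake ROI and
  whole-LV average less noisy (larger regions).  Gaussian scaling was chosen
  over Poisson resampling because frames hold reconstructed concentrations,
  not raw counts.  The reference-duration normalization keeps noise matched
  per unit time when the frame schedule changes.
* **Protocol**: rest/stress × test/retest with 5% CV physiologic flow
  jitter between repeats, 15% between-subject flow variation, and
  rate-pressure products correlated with achieved flow around 8240 (rest)
  and 10638 (stress) bpm·mmHg.
* **Delay**: true transport delay 1.5 s (order of 1–2 cardiac cycles).

What the generator does *not* emulate: voxel geometry and ROI placement
(the ROI choice is abstracted to (β, noise) differences), patient motion,
scanner dead time, reconstruction artefacts, and any condition-dependence of
the test–retest physiologic jitter.  Passing tests therefore demonstrate
self-consistency of the analysis chain under the stated statistical
structure, not performance on real images.  One visible consequence: the
generator's jitter CV is the same at rest and stress, so simulated stress
repeatability is not relatively better than rest, unlike the clinical
report.

## Statistics

Repeatability coefficients: RPC = 1.96 × SD (ddof 1) and RPC_np = 1.45 × IQR
with type-7 (linear interpolation) quartiles; 1.45 is 1.96 divided by the
standard-normal IQR (2 × 0.6745), so the two coincide for Gaussian
differences.  Per-condition median differences are removed before computing
coefficients; relative differences are percentages of the pair means, with
nonpositive pair means excluded.  Bland–Altman limits are mean ± 1.96 SD and,
nonparametrically, median ± RPC_np/2.  Between-variant comparisons use the
paired Wilcoxon signed-rank test on |centered differences| (exact null for
≤ 25 nonzero pairs) and the Brown–Forsythe (median-centered Levene) test on
centered differences, each variant against the reference; p-values are
unadjusted, as is conventional for this analysis.  Territory values pool
subjects × conditions × three territories as independent rows.

Injection QA fits a peak-normalized gamma-variate
`A·((t−t0)/(ατ))^α·e^{α−(t−t0)/τ}` to the first-pass frames of the blood TAC
(start < 90 s; the plateau is not gamma-shaped and drags the shape
parameters if included).  Transit metrics are defined as t_rise = ατ,
t_clearance = τ, t_mean_transit = (α+1)τ.  A scan is excluded when any
metric deviates from the cohort median by more than 3× the scaled MAD *and*
more than 50% of the median — the materiality floor prevents tightly
clustered clean cohorts from flagging unremarkable scans.

## Findings the test suite encodes

* **Delay**: the delay parameter hits its [0, 10] s bounds in roughly half
  of all sector fits at clinical noise on the 14-frame schedule
  (vs 57% reported clinically), and in only a slightly smaller fraction at
  1 s frames with count-matched noise.  The paired rebinning experiment
  (each study simulated at 1 s and the same acquisition rebinned to 14
  frames; 500 fits per seed) shows the coarse schedule is consistently worse
  (sign test over 10 seeds), but fine sampling does not rescue the delay
  model: the delay direction is nearly collinear with K1/FBV for a smooth
  tissue response, so nonconvergence is structural, not purely a sampling
  artefact.  Delay-off variants essentially always converge (< 0.5%
  nonconvergence).
* **Spillover correction**: with per-scan contamination jitter present,
  SOC-On pooled MBF RPC_np is below SOC-Off in most 12-subject cohorts
  (8/10 at the tested seeds), with a modest mean margin — bounded by the β
  estimator's information limit discussed above.  With an oracle β the
  margin is similar, indicating the estimator is near that limit.
* **Recovery**: on model-consistent noise-free studies the reference
  pipeline returns territory MBF within 3% (typically < 1%); extraction
  calibration recovers both coefficient sets to within 0.01 from exact
  pairs.

## Problem sizes

Default polar maps carry 496 sectors (half septal; LAD/LCX/RCA angular
wedges).  The stochastic suites run reduced sizes chosen for statistical
power per unit compute: 24–125 sectors per map, 3–12 subjects per cohort,
10 seeds per experiment.  The 12-subject cohorts in the spillover comparison
match the clinical study size.

## Known limitations

* β identifiability rests entirely on the recirculation-plateau prior; if
  real data violate the assumed plateau fraction, β (and MBF scale) inherit
  that error.  The prior constant is configurable (`SocConfig.late_fraction`).
* The ROI-choice axis is modeled only through (β, noise); geometric effects
  of ROI placement are out of scope, so Uptake-vs-Blood ROI differences in
  simulation are milder than anatomical reality.
* Clinical headline values (e.g. pooled RPC_np = 0.21 mL/min/g) derive from
  a private patient cohort and are scale references, not reproduction
  targets; the synthetic cohorts reproduce directions and orders of
  magnitude, not those exact numbers.
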