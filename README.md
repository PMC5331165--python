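# rbflow

Kinetic-model variant analysis and test–retest repeatability for myocardial
blood flow (MBF) quantification with dynamic ⁸²Rb PET.

Quantifying MBF from a dynamic rubidium scan involves a chain of modelling
choices: how the arterial input function is sampled, whether it is corrected
for myocardium-to-blood spillover, whether right-ventricular blood spillover
is modelled in the septum, whether the distribution volume is fit per sector
or fixed globally, and whether an arterial transport delay is included.
Each choice defines a variant of the one-tissue-compartment model, and the
variants differ in how *repeatable* their flow estimates are between
back-to-back scans — which is what matters for detecting disease progression
or treatment response.  `rbflow` implements all 32 variants, a synthetic
test–retest study generator with known ground truth, and the nonparametric
repeatability statistics to rank them.  It is aimed at researchers in
quantitative cardiac PET who want a transparent, fully testable reference
implementation of this analysis chain.

## The model

Myocardial tissue activity follows the one-tissue-compartment model

    C_t(t) = K1 · exp(−k2 (t − Δ)) ⊗ C_b(t),      k2 = K1 / DV

with uptake rate K1 (mL/min/g), washout k2 (1/min), distribution volume DV
(mL/g) and optional transport delay Δ ∈ [0, 10] s.  The image-sampled sector
signal mixes tissue with blood through the fractional blood volume,

    C_myo = FBV · C_b + RVBV · C_rv + (1 − FBV − RVBV) · C_t

(RVBV only in septal sectors when right-blood correction is on).  The dual
spillover correction treats the sampled blood-pool and whole-LV TACs as
complementary mixtures of pure blood and pure tissue with pure-blood
fraction β, and inverts that mixture to recover the input.  K1 converts to
flow through a flow-dependent extraction function
K1 = (1 − a·e^(−b/MBF))·MBF, with presets (a = 0.77, b = 0.63) for the
uncorrected input and (a = 0.76, b = 0.40) for the spillover-corrected path.

Repeatability of test–retest differences is summarized by the nonparametric
repeatability coefficient RPC_np = 1.45 × IQR (and the parametric
RPC = 1.96 × SD), after forcing per-condition median differences to zero.

## Worked example

```python
import dataclasses
from rbflow import (SyntheticStudyConfig, make_study, fit_study,
                    REFERENCE_VARIANT)

study = make_study(SyntheticStudyConfig(n_sectors=64), seed=7, subject_id="S01")
flows = fit_study(study, REFERENCE_VARIANT)

print("true rest MBF:", {k: round(v, 2) for k, v in
                         study.true_territory_mbf("rest", "test").items()})
print("fit  rest MBF:", {k: round(v, 2) for k, v in
                         flows.territory_mbf("rest", "test").items()})
print("MFR:", {k: round(v, 2) for k, v in flows.mfr("test").items()})

rbc_on = dataclasses.replace(REFERENCE_VARIANT, rbc=True)
print("rbc-on rest MBF:", {k: round(v, 2) for k, v in
                           fit_study(study, rbc_on).territory_mbf("rest", "test").items()})
```

prints (seed 7):

```
true rest MBF: {'LAD': 0.94, 'LCX': 0.85, 'RCA': 0.88}
fit  rest MBF: {'LAD': 0.81, 'LCX': 0.63, 'RCA': 0.79}
MFR: {'LAD': 2.52, 'LCX': 2.68, 'RCA': 2.89}
rbc-on rest MBF: {'LAD': 0.88, 'LCX': 0.79, 'RCA': 0.81}
```

The reference variant (Blood-ROI input, spillover correction on, right
blood correction off, global DV, no delay) recovers LAD and RCA flows well
at clinical noise levels, and the stress-to-rest flow reserve (MFR ≈ 2.5–2.9)
reflects the simulated dipyridamole response.  The LCX territory — entirely
septal in the default layout — is biased low because this study was
simulated with right-ventricular blood spilling into septal sectors, which
the reference variant deliberately ignores; switching the right-blood
correction on (`rbc=True`) largely removes that bias.  Accuracy and
repeatability are different axes: the comparison pipeline ranks variants by
the latter.

The command line covers the same workflow on study directories:

```bash
rbflow simulate --subjects 2 --seed 7 --out cohort
rbflow fit cohort/S01
rbflow qa cohort
rbflow compare cohort          # 17-variant repeatability table
```

`compare` writes `comparison.csv`/`.json` with one row per model variant:
RPC_np (absolute and % of pair means) for MBF at rest, stress and pooled,
MFR and ΔMBF, Spearman correlation, and Wilcoxon/Levene p-values against
the reference variant.

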