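"""Variant-comparison experiment: fit a cohort with every model variant and
rank the variants by test-retest repeatability.

For each variant the cohort's studies are fit, territory-level MBF / MFR /
delta-MBF values are paired test vs retest (subjects x conditions x three
coronary territories as independent rows), per-condition median bias is
removed, and the nonparametric repeatability coefficient is computed in
absolute units and relative to the pair means.  Each variant's centered
differences are compared to the reference variant's with a paired Wilcoxon
test on their magnitudes (median precision) and a Brown-Forsythe Levene
test (spread).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fitting import (
    DELAY_COMBINATION,
    FitConfig,
    StudyFlows,
    Study,
    fit_study,
    nonconvergence_rate,
)
from .model import ModelVariant, REFERENCE_VARIANT, TERRITORIES, variant_catalog
from .qa import NoPeakError, fit_gamma_variate, flag_outlier_scans, transit_metrics
from .repeatability import (
    bland_altman,
    levene_p,
    median_center,
    relative_differences,
    rpc,
    rpc_np,
    spearman_rho,
    wilcoxon_p,
)

__all__ = [
    "paper_preset_variants",
    "assemble_pairs",
    "variant_statistics",
    "qa_screen",
    "run_comparison",
]


def paper_preset_variants() -> list[ModelVariant]:
    """The 16 delay-off variants plus the single delay-on combination (17 rows)."""
    return variant_catalog(allow_delay=False) + [DELAY_COMBINATION]


# ---------------------------------------------------------------------------
# paired measurements
# ---------------------------------------------------------------------------


def assemble_pairs(flows_by_study: list[StudyFlows]) -> pd.DataFrame:
    """Tidy test/retest pairs: one row per subject x metric x condition x territory.

    Metrics: 'mbf' (per condition), 'mfr' and 'dmbf' (stress/rest composites,
    labeled condition='both').
    """
    rows = []
    for sf in flows_by_study:
        for condition in ("rest", "stress"):
            t1 = sf.territory_mbf(condition, "test")
            t2 = sf.territory_mbf(condition, "retest")
            for terr in TERRITORIES:
                rows.append((sf.subject_id, "mbf", condition, terr, t1[terr], t2[terr]))
        for metric, f in (("mfr", sf.mfr), ("dmbf", sf.delta_mbf)):
            v1, v2 = f("test"), f("retest")
            for terr in TERRITORIES:
                rows.append((sf.subject_id, metric, "both", terr, v1[terr], v2[terr]))
    return pd.DataFrame(
        rows, columns=["subject", "metric", "condition", "territory", "test", "retest"]
    )


def _centered_diffs(pairs: pd.DataFrame, metric: str, condition: str | None) -> np.ndarray:
    sub = pairs[pairs.metric == metric]
    if condition is not None:
        sub = sub[sub.condition == condition]
    d = (sub.retest - sub.test).to_numpy()
    return median_center(d, sub.condition.to_numpy())


def _centered_rel_diffs(pairs: pd.DataFrame, metric: str, condition: str | None) -> np.ndarray:
    sub = pairs[pairs.metric == metric]
    if condition is not None:
        sub = sub[sub.condition == condition]
    pct, kept = relative_differences(sub.test.to_numpy(), sub.retest.to_numpy())
    return median_center(pct, sub.condition.to_numpy()[kept])


def variant_statistics(pairs: pd.DataFrame) -> dict:
    """Repeatability summary for one variant's paired measurements."""
    out = {}
    for metric, conditions in (("mbf", ("rest", "stress", None)), ("mfr", (None,)), ("dmbf", (None,))):
        for condition in conditions:
            tag = condition or ("pooled" if metric == "mbf" else "")
            name = f"{metric}_{tag}".rstrip("_")
            d = _centered_diffs(pairs, metric, condition)
            rel = _centered_rel_diffs(pairs, metric, condition)
            out[f"rpc_np_{name}"] = rpc_np(d)
            out[f"rpc_np_{name}_rel"] = rpc_np(rel)
            out[f"rpc_{name}"] = rpc(d)
            out[f"rpc_{name}_rel"] = rpc(rel)
    mbf = pairs[pairs.metric == "mbf"]
    out["spearman_mbf"] = spearman_rho(mbf.test.to_numpy(), mbf.retest.to_numpy())
    ba = bland_altman(mbf.test.to_numpy(), mbf.retest.to_numpy(), relative=True)
    out["bland_altman_mean_rel"] = ba.mean_difference
    out["bland_altman_lower_rel"] = ba.lower
    out["bland_altman_upper_rel"] = ba.upper
    return out


# ---------------------------------------------------------------------------
# QA screening
# ---------------------------------------------------------------------------


def qa_screen(cohort: list[Study]) -> pd.DataFrame:
    """Gamma-variate QA over every scan of the cohort.

    Returns one row per scan with the fitted bolus parameters, transit
    metrics and an ``excluded`` flag for cohort outliers (or unfittable
    blood TACs).
    """
    rows, index = [], []
    for study in cohort:
        for scan in study.scans:
            index.append((study.subject_id, scan.condition, scan.repeat))
            try:
                fit = fit_gamma_variate(scan.blood_roi)
                m = transit_metrics(fit)
                rows.append(
                    dict(
                        amplitude=fit.amplitude,
                        t0=fit.t0,
                        alpha=fit.alpha,
                        tau=fit.tau,
                        t_rise=m.t_rise,
                        t_clearance=m.t_clearance,
                        t_mean_transit=m.t_mean_transit,
                        fit_failed=False,
                    )
                )
            except (NoPeakError, RuntimeError):
                rows.append(
                    dict(
                        amplitude=np.nan, t0=np.nan, alpha=np.nan, tau=np.nan,
                        t_rise=np.nan, t_clearance=np.nan, t_mean_transit=np.nan,
                        fit_failed=True,
                    )
                )
    df = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["subject", "condition", "repeat"])
    )
    ok = ~df.fit_failed
    df["excluded"] = True
    if ok.sum() >= 4:
        flags = flag_outlier_scans(df.loc[ok, ["t_rise", "t_clearance", "t_mean_transit"]])
        df.loc[ok, "excluded"] = flags
    elif ok.any():
        df.loc[ok, "excluded"] = False
    return df


# ---------------------------------------------------------------------------
# the comparison experiment
# ---------------------------------------------------------------------------


def run_comparison(
    cohort: list[Study],
    variants: list[ModelVariant] | None = None,
    reference: ModelVariant = REFERENCE_VARIANT,
    config: FitConfig | None = None,
    qa_filter: bool = True,
) -> pd.DataFrame:
    """Fit every variant on the cohort and tabulate repeatability vs the reference.

    Returns one row per variant: RPC_np (absolute and % of pair means) for
    MBF rest/stress/pooled, MFR and delta-MBF; Spearman correlation;
    Wilcoxon and Levene p-values of the pooled centered MBF differences
    versus the reference variant; and nonconvergence rates.  Deterministic
    given the cohort and configuration.
    """
    variants = variants if variants is not None else paper_preset_variants()
    if reference not in variants:
        raise ValueError("the reference variant must be among the compared variants")
    if len(cohort) < 2:
        raise ValueError("need a cohort of at least 2 subjects")
    config = config or FitConfig()

    excluded: set[tuple[str, str, str]] = set()
    if qa_filter:
        qa = qa_screen(cohort)
        excluded = set(qa.index[qa.excluded])

    def keep_study(study: Study) -> Study:
        kept = [s for s in study.scans if (study.subject_id, s.condition, s.repeat) not in excluded]
        return Study(study.subject_id, kept)

    filtered = []
    for study in cohort:
        st = keep_study(study)
        have = {(s.condition, s.repeat) for s in st.scans}
        if {("rest", "test"), ("rest", "retest"), ("stress", "test"), ("stress", "retest")} <= have:
            filtered.append(st)
    if len(filtered) < 2:
        raise ValueError("fewer than 2 subjects survive QA screening")

    cache: dict = {}
    rows = []
    diffs: dict[ModelVariant, np.ndarray] = {}
    for variant in variants:
        row: dict = {"variant": variant.key, "label": variant.label}
        try:
            flows = [fit_study(s, variant, config, input_cache=cache) for s in filtered]
            pairs = assemble_pairs(flows)
            row.update(variant_statistics(pairs))
            fits = [f for sf in flows for f in sf.all_fits()]
            row["nonconv_any"] = nonconvergence_rate(fits, "any")
            row["nonconv_delay"] = nonconvergence_rate(fits, "delay") if variant.delay else 0.0
            diffs[variant] = _centered_diffs(pairs, "mbf", None)
        except Exception as exc:  # record per-variant failures, keep going
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)

    ref_d = diffs.get(reference)
    for row in rows:
        v = next(v for v in variants if v.key == row["variant"])
        d = diffs.get(v)
        if ref_d is None or d is None or d.size != ref_d.size:
            row["wilcoxon_p_vs_ref"] = np.nan
            row["levene_p_vs_ref"] = np.nan
            continue
        if v == reference:
            row["wilcoxon_p_vs_ref"] = 1.0
            row["levene_p_vs_ref"] = 1.0
            continue
        try:
            row["wilcoxon_p_vs_ref"] = wilcoxon_p(np.abs(ref_d), np.abs(d))
        except ValueError:
            row["wilcoxon_p_vs_ref"] = 1.0
        try:
            row["levene_p_vs_ref"] = levene_p(ref_d, d)
        except ValueError:
            row["levene_p_vs_ref"] = 1.0

    table = pd.DataFrame(rows)
    return table
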