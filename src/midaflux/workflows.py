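"""Study-level workflows built on the rollup and statistics layers.

These functions consume the filtered protein FSR table (one row per protein
per sample, with group/day metadata attached) and reproduce the standard
analyses: a two-arm flux comparison at one time point, the full time course
against a reference day, and the WPASR table.
"""

from __future__ import annotations

import pandas as pd

from . import rollup, stats


def _arm_summary(proteins: pd.DataFrame, arm: str, day: float | None) -> pd.DataFrame:
    sub = proteins[proteins["group"] == arm]
    if day is not None:
        sub = sub[sub["day"] == day]
    if sub.empty:
        raise ValueError(f"no protein records for arm {arm!r} at day {day}")
    return rollup.group_summary(sub[["protein_id", "fsr"]], group_label=arm)


def compare_arms(
    proteins: pd.DataFrame,
    arm_ref: str = "Con",
    arm_alt: str = "CR",
    day: float | None = None,
    binomial_method: str = "double",
    cv_threshold: float | None = None,
) -> tuple[pd.DataFrame, stats.ProportionTestResult, float]:
    """Full two-arm comparison: log2FCs, CV cutoff, classification, sign test.

    The stringency threshold defaults to the average of all defined per-
    protein CVs pooled over both arms; pass ``cv_threshold`` to override.
    Returns the per-protein comparison table, the Up/Down proportion test
    and the threshold used.
    """
    summary_ref = _arm_summary(proteins, arm_ref, day)
    summary_alt = _arm_summary(proteins, arm_alt, day)
    comp = stats.paired_log2fc(
        summary_ref[["protein_id", "mean_fsr", "cv"]],
        summary_alt[["protein_id", "mean_fsr", "cv"]],
    )
    if cv_threshold is None:
        cv_threshold = stats.average_cv_threshold(summary_ref["cv"], summary_alt["cv"])
    comp = stats.classify_flux_change(comp, cv_threshold)
    result = stats.proportion_test(comp, method=binomial_method)
    return comp, result, cv_threshold


def timecourse(
    proteins: pd.DataFrame,
    arm_ref: str = "Con",
    arm_alt: str = "CR",
    reference_day: float = 0.0,
    binomial_method: str = "double",
    threshold_pct_down: float = 70.0,
) -> tuple[pd.DataFrame, stats.TimecourseResult]:
    """Per-day Up/Down proportions and the transition-day estimate."""
    days = sorted(proteins["day"].unique())
    rows = []
    for day in days:
        comp, res, thr = compare_arms(
            proteins, arm_ref, arm_alt, day=day, binomial_method=binomial_method
        )
        rows.append(
            {
                "day": day,
                "n_down": res.n_down,
                "n_up": res.n_up,
                "n_ties": res.n_ties,
                "pct_down": res.pct_down,
                "pct_down_above_cv": res.pct_down_above_cv,
                "p_binomial": res.p_binomial,
                "cv_threshold": thr,
            }
        )
    daily = pd.DataFrame(rows)
    summary = stats.timecourse_summary(
        daily, reference_day=reference_day, threshold_pct_down=threshold_pct_down
    )
    return daily, summary


def wpasr_table(proteins: pd.DataFrame, intensities: pd.DataFrame) -> pd.DataFrame:
    """Per-protein WPASR for every sample, from FSRs and label-free intensities.

    ``intensities`` columns: protein_id, sample_id, intensity.  Returns
    protein_id, sample_id, q, wpasr.
    """
    merged = proteins.merge(intensities, on=["protein_id", "sample_id"], how="inner")
    out = []
    for sample_id, grp in merged.groupby("sample_id"):
        q = rollup.intensity_quotient(grp["intensity"])
        sub = grp[["protein_id", "sample_id", "fsr"]].copy()
        sub["q"] = q
        sub["wpasr"] = rollup.wpasr(grp["fsr"], q)
        out.append(sub)
    return pd.concat(out, ignore_index=True)
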