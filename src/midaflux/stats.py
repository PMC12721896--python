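"""Proteome-wide flux comparison statistics.

The comparison machinery: per-protein log2 fold changes of group-mean FSRs
between two study arms, Up/Down classification with a pooled-average-CV
stringency cutoff, an exact two-tailed binomial (sign) test on the Up/Down
split, Fisher's exact test contrasting down-regulation prevalence between
arms, per-timepoint z-score standardization, and the time-course summary
with logistic transition-day estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


# ---------------------------------------------------------------------------
# fold changes and classification

def paired_log2fc(
    summary_ref: pd.DataFrame, summary_alt: pd.DataFrame
) -> pd.DataFrame:
    """Per-protein log2(FSR_alt / FSR_ref) for proteins present in both arms.

    Inputs are group summaries (protein_id, mean_fsr, cv columns).  Proteins
    missing from either arm or with a non-positive mean in either arm are
    excluded.  Returns protein_id, log2fc, percent_change, direction
    ({Up, Down, Tie}) plus both arms' CVs for downstream cutoffs.
    """
    merged = summary_ref.merge(
        summary_alt, on="protein_id", suffixes=("_ref", "_alt"), how="inner"
    )
    merged = merged[(merged["mean_fsr_ref"] > 0) & (merged["mean_fsr_alt"] > 0)]
    out = pd.DataFrame({"protein_id": merged["protein_id"]})
    out["log2fc"] = np.log2(merged["mean_fsr_alt"].to_numpy() / merged["mean_fsr_ref"].to_numpy())
    out["percent_change"] = (np.exp2(out["log2fc"]) - 1.0) * 100.0
    out["direction"] = np.select(
        [out["log2fc"] > 0, out["log2fc"] < 0], ["Up", "Down"], default="Tie"
    )
    for col in ("cv_ref", "cv_alt"):
        if col in merged.columns:
            out[col] = merged[col].to_numpy()
    return out.reset_index(drop=True)


def average_cv_threshold(*cv_sets: pd.Series | np.ndarray) -> float:
    """Unweighted mean of all defined per-protein CVs pooled over the arms."""
    pooled = np.concatenate([np.asarray(c, dtype=float).ravel() for c in cv_sets])
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("no defined CVs to average")
    return float(pooled.mean())


def classify_flux_change(comparisons: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Flag changes whose |percent change| exceeds the CV-derived threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = comparisons.copy()
    out["above_cv"] = np.abs(out["percent_change"].to_numpy()) > threshold
    return out


# ---------------------------------------------------------------------------
# exact tests

def binomial_two_tailed(
    n_down: int, n_total: int, p0: float = 0.5, method: str = "double"
) -> float:
    """Exact two-tailed binomial (sign-test) p-value for an Up/Down split.

    ``method='double'`` doubles the smaller tail probability and caps at 1
    (the coin-toss convention); ``method='minlike'`` sums all outcomes at
    most as likely as the observed one.
    """
    if not 0 <= n_down <= n_total:
        raise ValueError(f"need 0 <= n_down <= n_total, got {n_down}/{n_total}")
    if n_total == 0:
        raise ValueError("no classified proteins: binomial test undefined")
    if method == "minlike":
        return float(sps.binomtest(n_down, n_total, p0, alternative="two-sided").pvalue)
    if method != "double":
        raise ValueError(f"unknown method {method!r}")
    dist = sps.binom(n_total, p0)
    lower = dist.cdf(n_down)
    upper = dist.sf(n_down - 1)
    return float(min(1.0, 2.0 * min(lower, upper)))


def fisher_exact_two_tailed(table: np.ndarray | list[list[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (hypergeometric sum)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate margins: Fisher's exact test undefined")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


@dataclass
class ProportionTestResult:
    """Up/Down split of a proteome comparison with its binomial p-value."""

    n_down: int
    n_up: int
    n_ties: int
    p_binomial: float
    n_down_above_cv: int = 0
    n_up_above_cv: int = 0

    @property
    def n_classified(self) -> int:
        return self.n_down + self.n_up

    @property
    def pct_down(self) -> float:
        return 100.0 * self.n_down / self.n_classified if self.n_classified else float("nan")

    @property
    def pct_down_above_cv(self) -> float:
        return (
            100.0 * self.n_down_above_cv / self.n_classified
            if self.n_classified
            else float("nan")
        )

    @property
    def pct_up_above_cv(self) -> float:
        return (
            100.0 * self.n_up_above_cv / self.n_classified if self.n_classified else float("nan")
        )


def proportion_test(comparisons: pd.DataFrame, method: str = "double") -> ProportionTestResult:
    """Count Up/Down calls (ties excluded) and run the two-tailed binomial test."""
    direction = comparisons["direction"]
    n_down = int((direction == "Down").sum())
    n_up = int((direction == "Up").sum())
    n_ties = int((direction == "Tie").sum())
    above = comparisons["above_cv"] if "above_cv" in comparisons else pd.Series(False, index=comparisons.index)
    p = binomial_two_tailed(n_down, n_down + n_up, method=method) if n_down + n_up else float("nan")
    return ProportionTestResult(
        n_down=n_down,
        n_up=n_up,
        n_ties=n_ties,
        p_binomial=p,
        n_down_above_cv=int(((direction == "Down") & above).sum()),
        n_up_above_cv=int(((direction == "Up") & above).sum()),
    )


@dataclass
class ArmContrast:
    """2x2 contrast of down-regulation prevalence between two arms."""

    arm_a: str
    arm_b: str
    table: np.ndarray  # rows: arm; cols: (down, not down)
    p_fisher: float


def arm_contrast(
    result_a: ProportionTestResult,
    result_b: ProportionTestResult,
    arm_a: str = "A",
    arm_b: str = "B",
) -> ArmContrast:
    """Fisher's exact comparison of Down vs not-Down proportions between arms."""
    table = np.array(
        [
            [result_a.n_down, result_a.n_up],
            [result_b.n_down, result_b.n_up],
        ]
    )
    return ArmContrast(arm_a, arm_b, table, fisher_exact_two_tailed(table))


# ---------------------------------------------------------------------------
# standardization and time course

def zscore(values: np.ndarray | pd.Series) -> np.ndarray:
    """Standard scores with sample SD; rejects constant input."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-scores undefined")
    return (arr - arr.mean()) / sd


def zscore_by_timepoint(
    records: pd.DataFrame, value_col: str = "mean_fsr", pooled: bool = True
) -> pd.DataFrame:
    """Standardize FSRs within each time point, pooled across arms by default.

    ``records`` columns: day, group, and ``value_col``.  With ``pooled=False``
    each arm is standardized against its own mean and SD.
    """
    by = ["day"] if pooled else ["day", "group"]
    out = records.copy()
    out["zscore"] = (
        out.groupby(by)[value_col].transform(lambda v: zscore(v.to_numpy()))
    )
    return out


def _logistic4(day: np.ndarray, lower: float, upper: float, midpoint: float, scale: float) -> np.ndarray:
    z = np.clip(-(day - midpoint) / scale, -700, 700)
    return lower + (upper - lower) / (1.0 + np.exp(z))


@dataclass
class TimecourseResult:
    """Per-day down-regulation prevalence and the estimated transition day."""

    points: pd.DataFrame
    transition_day: float | None
    first_day_above_threshold: float | None
    threshold: float
    fit_params: dict[str, float] = field(default_factory=dict)


def timecourse_summary(
    daily: pd.DataFrame,
    reference_day: float = 0.0,
    threshold_pct_down: float = 70.0,
) -> TimecourseResult:
    """Summarize percent-down across days and locate the transition.

    ``daily`` columns: day, pct_down and optionally pct_down_above_cv.  Adds
    log2 ratios of pct_down to the reference day (both sign conventions).
    The transition day is the midpoint of a 4-parameter logistic fitted to
    pct_down vs day; a flat series (no rise beyond 2 points of percent)
    yields no transition.  Also reports the first day whose pct_down exceeds
    ``threshold_pct_down``.
    """
    if len(daily) < 3:
        raise ValueError("need at least three time points")
    days = daily["day"].to_numpy(dtype=float)
    if reference_day not in days:
        raise ValueError(f"reference day {reference_day} not present")
    pct = daily["pct_down"].to_numpy(dtype=float)
    ref = pct[days == reference_day][0]
    points = daily.sort_values("day").reset_index(drop=True).copy()
    with np.errstate(divide="ignore"):
        ratio = np.log2(points["pct_down"].to_numpy() / ref)
    points["log2_rel_day0"] = ratio
    points["neg_log2_rel_day0"] = -ratio

    transition: float | None = None
    fit_params: dict[str, float] = {}
    if pct.max() - pct.min() > 2.0:
        d = points["day"].to_numpy(dtype=float)
        y = points["pct_down"].to_numpy(dtype=float)
        p0 = [y.min(), y.max(), float(np.median(d)), max(1.0, (d.max() - d.min()) / 10)]
        try:
            popt, _ = optimize.curve_fit(
                _logistic4,
                d,
                y,
                p0=p0,
                bounds=([0.0, 0.0, d.min(), 1e-3], [100.0, 100.0, d.max(), d.max()]),
                maxfev=20000,
            )
            fit_params = dict(zip(("lower", "upper", "midpoint", "scale"), map(float, popt)))
            transition = fit_params["midpoint"]
        except RuntimeError:
            transition = None

    above = points.loc[points["pct_down"] > threshold_pct_down, "day"]
    first_above = float(above.iloc[0]) if len(above) else None
    return TimecourseResult(
        points=points,
        transition_day=transition,
        first_day_above_threshold=first_above,
        threshold=threshold_pct_down,
        fit_params=fit_params,
    )
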