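"""Protein-level rollup of peptide kinetics and WPASR normalization.

Peptide fractional synthesis values are aggregated to one FSR per protein per
animal (spectral-count-weighted mean by default), filtered by the minimum
spectral evidence rule, and summarized per study arm (mean, SD, CV).  WPASR
(within-proteome absolute synthesis rate) multiplies each protein's FSR by
its normalized label-free intensity quotient Q within the sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: minimum peptide spectra per protein per sample (measurements below are excluded)
MIN_SPECTRA = 2


def filter_min_spectra(
    records: pd.DataFrame, min_spectra: int = MIN_SPECTRA, per_sample: bool = True
) -> pd.DataFrame:
    """Drop protein measurements with fewer than ``min_spectra`` peptide spectra.

    ``records`` must carry protein_id, sample_id and n_spectra columns.  The
    rule is applied per protein per sample by default; with
    ``per_sample=False`` spectra are summed over samples before the cut.
    """
    if records.empty:
        return records
    if per_sample:
        keep = records["n_spectra"] >= min_spectra
    else:
        totals = records.groupby("protein_id")["n_spectra"].transform("sum")
        keep = totals >= min_spectra
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_min_spectra removed %d of %d records", removed, len(records))
    return records.loc[keep].copy()


def protein_fsr(peptides: pd.DataFrame, method: str = "weighted_mean") -> pd.DataFrame:
    """Aggregate peptide f values to protein-level FSRs per sample.

    ``peptides`` columns: protein_id, sample_id, f, spectral_count and an
    optional boolean qc_ok.  QC-flagged peptides are dropped; proteins whose
    peptides are all flagged are dropped entirely (they carry no estimate).
    Returns protein_id, sample_id, fsr, n_peptides, n_spectra.
    """
    if method not in {"weighted_mean", "mean", "median"}:
        raise ValueError(f"unknown aggregation method {method!r}")
    df = peptides
    if "qc_ok" in df.columns:
        df = df[df["qc_ok"]]
    if df.empty:
        return pd.DataFrame(columns=["protein_id", "sample_id", "fsr", "n_peptides", "n_spectra"])

    def _agg(group: pd.DataFrame) -> pd.Series:
        if method == "weighted_mean":
            fsr = np.average(group["f"], weights=group["spectral_count"])
        elif method == "mean":
            fsr = group["f"].mean()
        else:
            fsr = group["f"].median()
        return pd.Series(
            {
                "fsr": fsr,
                "n_peptides": len(group),
                "n_spectra": int(group["spectral_count"].sum()),
            }
        )

    out = (
        df.groupby(["protein_id", "sample_id"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_peptides"] = out["n_peptides"].astype(int)
    out["n_spectra"] = out["n_spectra"].astype(int)
    return out


def group_summary(records: pd.DataFrame, group_label: str | None = None) -> pd.DataFrame:
    """Per-protein mean/SD/CV of FSR across the animals of one group.

    ``records`` columns: protein_id, fsr (one row per animal).  Proteins seen
    in fewer than two animals, or with non-positive mean FSR, get NaN CV and
    cv_defined=False.  SD uses the n-1 denominator; CV is in percent.
    """
    g = records.groupby("protein_id")["fsr"]
    out = pd.DataFrame(
        {"mean_fsr": g.mean(), "sd_fsr": g.std(ddof=1), "n_animals": g.size()}
    ).reset_index()
    ok = (out["n_animals"] >= 2) & (out["mean_fsr"] > 0)
    out["cv"] = np.where(ok, 100.0 * out["sd_fsr"] / out["mean_fsr"], np.nan)
    out["cv_defined"] = ok
    if group_label is not None:
        out.insert(1, "group", group_label)
    return out


def intensity_quotient(intensities: pd.Series | np.ndarray) -> np.ndarray:
    """Normalized signal intensity quotient Q within one sample (sums to 1)."""
    arr = np.asarray(intensities, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative intensity")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all intensities are zero")
    return arr / total


def wpasr(fsr: pd.Series | np.ndarray, q: pd.Series | np.ndarray) -> np.ndarray:
    """Within-proteome absolute synthesis rate: FSR x Q."""
    return np.asarray(fsr, float) * np.asarray(q, float)


def normalize_wpasr_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Normalize a proteins x samples WPASR matrix for cross-sample comparison.

    Each sample is divided by its median (systemic differences), values are
    log10-transformed, and each protein row is centered to mean zero.
    Non-positive entries are masked to NaN rather than imputed.
    """
    mat = matrix.astype(float).where(matrix > 0)
    medians = mat.median(axis=0, skipna=True)
    if medians.isna().any() or (medians <= 0).any():
        bad = medians.index[medians.isna() | (medians <= 0)].tolist()
        raise ValueError(f"samples with no usable values: {bad}")
    mat = np.log10(mat / medians)
    return mat.sub(mat.mean(axis=1, skipna=True), axis=0)
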