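"""Table readers/writers and run configuration.

All tables are UTF-8, tab-separated, with a mandatory header row and empty
fields for missing values; probabilities are printed in scientific notation
with six significant digits so the full dynamic range survives round trips.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PEPTIDE_COLUMNS = ["sequence", "protein_id", "sample_id", "spectral_count", "m0", "m1", "m2", "m3"]
METADATA_COLUMNS = ["sample_id", "animal", "group", "day", "p_body"]


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    peptides: str | None = None
    metadata: str | None = None
    intensities: str | None = None
    site_table: str | None = None
    p_natural: float = 0.000115
    aggregation: str = "weighted_mean"
    min_spectra: int = 2
    binomial_method: str = "double"
    cv_pooling: str = "both_arms"
    timecourse_threshold: float = 70.0
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read a measured peptide envelope table, validating and renormalizing.

    Rows with negative abundances or an all-zero envelope are dropped with a
    logged line number; envelopes are renormalized over M0-M3 on read.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table {path} missing required column(s): {missing}")
    env = df[["m0", "m1", "m2", "m3"]].to_numpy(dtype=float)
    bad = np.any(env < 0, axis=1) | (env.sum(axis=1) <= 0) | np.any(~np.isfinite(env), axis=1)
    for idx in np.flatnonzero(bad):
        logger.warning("%s line %d: invalid envelope, row dropped", path, idx + 2)
    df = df.loc[~bad].reset_index(drop=True)
    env = df[["m0", "m1", "m2", "m3"]].to_numpy(dtype=float)
    df[["m0", "m1", "m2", "m3"]] = env / env.sum(axis=1, keepdims=True)
    df["spectral_count"] = df["spectral_count"].astype(int)
    return df


def read_metadata(path: str | Path, peptides: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read the sample metadata table and validate it against the peptide table."""
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata {path} missing required column(s): {missing}")
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample IDs in metadata: {sorted(dup.unique())}")
    if (meta["p_body"] <= 0).any():
        bad = meta.loc[meta["p_body"] <= 0, "sample_id"].tolist()
        raise ValueError(f"samples with non-positive body water enrichment: {bad}")
    if peptides is not None:
        unmapped = set(peptides["sample_id"]) - set(meta["sample_id"])
        if unmapped:
            raise ValueError(f"samples present in data but not metadata: {sorted(unmapped)}")
    return meta


def read_de_table(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc"):
        if col not in de.columns:
            raise ValueError(f"DE table {path} missing required column {col!r}")
    return de


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tab-separated table with full float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_reports(
    results: dict,
    outdir: str | Path,
    overwrite: bool = False,
) -> None:
    """Write result tables plus a JSON run summary to ``outdir``.

    ``results`` maps table names to DataFrames, with an optional "summary"
    entry (a JSON-serializable dict of counts and p-values).  Refuses to
    overwrite a populated directory unless asked.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    existing = list(outdir.glob("*.tsv")) + list(outdir.glob("*.json"))
    if existing and not overwrite:
        raise FileExistsError(f"{outdir} already contains results; pass overwrite=True")
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            write_table(obj, outdir / f"{name}.tsv")
        else:
            (outdir / f"{name}.json").write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def format_pvalue(p: float) -> str:
    """Scientific notation with six significant digits."""
    return f"{p:.6e}"
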