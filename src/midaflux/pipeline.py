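"""End-to-end glue: measured peptide envelopes -> protein FSR tables.

Envelope theory is cached per unique (sequence, enrichment) pair, so large
peptide tables re-use each peptide's baseline and asymptote instead of
re-convolving them per sample.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from . import rollup
from .chem import composition_from_sequence, exchangeable_site_count
from .mida import (
    IsotopeEnvelope,
    LabelingContext,
    baseline_and_asymptote,
    em0_excess_and_max,
    fractional_synthesis,
    truncate_and_renormalize,
)

ENVELOPE_COLS = ["m0", "m1", "m2", "m3"]


@lru_cache(maxsize=100_000)
def _envelope_pair(
    sequence: str, p_body: float, p_natural: float, k: int, site_table_key: tuple | None
):
    site_table = dict(site_table_key) if site_table_key is not None else None
    comp = composition_from_sequence(sequence)
    n = exchangeable_site_count(sequence, site_table)
    ctx = LabelingContext(p_body=p_body, p_natural=p_natural)
    return baseline_and_asymptote(comp, n, ctx, k)


def peptide_kinetics_table(
    peptides: pd.DataFrame,
    context: LabelingContext,
    site_table: dict[str, float] | None = None,
    k: int = 3,
) -> pd.DataFrame:
    """Compute per-row fractional synthesis for a measured peptide table.

    ``peptides`` columns: sequence, protein_id, sample_id, spectral_count and
    the envelope columns m0..m3.  Adds em0, em0_max, f and qc_ok.
    """
    key = tuple(sorted(site_table.items())) if site_table is not None else None
    out = peptides.copy()
    em0s = np.empty(len(out))
    em0_maxs = np.empty(len(out))
    fs = np.empty(len(out))
    ok = np.empty(len(out), dtype=bool)
    envelopes = out[ENVELOPE_COLS].to_numpy(dtype=float)
    for i, (seq, env) in enumerate(zip(out["sequence"], envelopes)):
        baseline, asymptote = _envelope_pair(seq, context.p_body, context.p_natural, k, key)
        measured = truncate_and_renormalize(IsotopeEnvelope(env), k)
        em0, em0_max = em0_excess_and_max(measured, baseline, asymptote)
        kin = fractional_synthesis(em0, em0_max)
        em0s[i], em0_maxs[i], fs[i], ok[i] = em0, em0_max, kin.f, kin.ok
    out["em0"] = em0s
    out["em0_max"] = em0_maxs
    out["f"] = fs
    out["qc_ok"] = ok
    return out


def run_fsr(
    peptides: pd.DataFrame,
    metadata: pd.DataFrame,
    context: LabelingContext,
    site_table: dict[str, float] | None = None,
    aggregation: str = "weighted_mean",
    min_spectra: int = rollup.MIN_SPECTRA,
) -> pd.DataFrame:
    """Peptide envelopes to filtered protein-level FSRs with sample metadata."""
    kinetics = peptide_kinetics_table(peptides, context, site_table)
    proteins = rollup.protein_fsr(kinetics, method=aggregation)
    proteins = rollup.filter_min_spectra(proteins, min_spectra=min_spectra)
    return proteins.merge(metadata, on="sample_id", how="left", validate="many_to_one")
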