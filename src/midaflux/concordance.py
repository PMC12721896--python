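"""Protein-flux vs mRNA direction concordance.

Matches per-protein FSR fold changes against a gene-level differential
expression table (log2FC signs taken as given; the DE modeling itself is
upstream of this package) and tests whether direction agreement departs
from the 50:50 expected under independence, using the same exact two-tailed
binomial test as the proteome comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .stats import binomial_two_tailed

logger = logging.getLogger(__name__)


def match_and_orient(
    flux_comparisons: pd.DataFrame,
    de_table: pd.DataFrame,
    mapping: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join FSR and mRNA fold changes and call each pair concordant or not.

    ``flux_comparisons``: protein_id, log2fc (FSR scale).  ``de_table``:
    gene_id, log2fc (mRNA scale).  ``mapping``: two columns gene_id,
    protein_id; omitted when the identifiers are shared.  Zero fold changes
    on either side carry no direction and are excluded, as are genes or
    proteins with ambiguous many-to-many mappings.
    """
    if flux_comparisons.empty or de_table.empty:
        raise ValueError("both the flux and DE tables must be non-empty")
    flux = flux_comparisons.rename(columns={"log2fc": "fsr_log2fc"})
    de = de_table.rename(columns={"log2fc": "mrna_log2fc"})
    if mapping is None:
        mapping = pd.DataFrame(
            {"gene_id": de["gene_id"], "protein_id": de["gene_id"]}
        )
    ambiguous = mapping["gene_id"].duplicated(keep=False) | mapping[
        "protein_id"
    ].duplicated(keep=False)
    if ambiguous.any():
        logger.info("excluding %d ambiguous mapping rows", int(ambiguous.sum()))
        mapping = mapping.loc[~ambiguous]

    joined = (
        flux[["protein_id", "fsr_log2fc"]]
        .merge(mapping, on="protein_id", how="inner")
        .merge(de[["gene_id", "mrna_log2fc"]], on="gene_id", how="inner")
    )
    n_lost = len(flux) - joined["protein_id"].nunique()
    if n_lost:
        logger.info("%d proteins had no matched gene", n_lost)
    joined = joined[(joined["fsr_log2fc"] != 0) & (joined["mrna_log2fc"] != 0)].copy()
    joined["fsr_direction"] = joined["fsr_log2fc"].map(lambda v: "Up" if v > 0 else "Down")
    joined["mrna_direction"] = joined["mrna_log2fc"].map(lambda v: "Up" if v > 0 else "Down")
    joined["concordant"] = joined["fsr_direction"] == joined["mrna_direction"]
    return joined.reset_index(drop=True)


@dataclass
class ConcordanceResult:
    n_concordant: int
    n_discordant: int
    p_binomial: float

    @property
    def n_total(self) -> int:
        return self.n_concordant + self.n_discordant

    @property
    def pct_concordant(self) -> float:
        return 100.0 * self.n_concordant / self.n_total if self.n_total else float("nan")


def concordance_test(records: pd.DataFrame, method: str = "double") -> ConcordanceResult:
    """Two-tailed binomial test of concordant vs discordant direction pairs."""
    if records.empty:
        raise ValueError("no matched records to test")
    n_conc = int(records["concordant"].sum())
    n_disc = int((~records["concordant"]).sum())
    p = binomial_two_tailed(n_conc, n_conc + n_disc, method=method)
    return ConcordanceResult(n_concordant=n_conc, n_discordant=n_disc, p_binomial=p)
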