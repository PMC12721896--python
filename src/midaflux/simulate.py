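"""Synthetic heavy-water labeling studies with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
cohort of replicate animals per study arm, per-protein baseline fractional
synthesis rates, a calorie-restriction effect that switches on logistically
around a transition day, tryptic-like peptides whose isotope envelopes are
exact baseline/asymptote mixtures at the true FSR, and multinomial ion-
counting noise on every measured envelope.  All randomness flows from one
integer seed through named per-component streams, so any table can be
regenerated bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import composition_from_sequence, exchangeable_site_count
from .lipids import PALMITATE, LipidSpecies
from .mida import LabelingContext, baseline_and_asymptote
from .stats import binomial_two_tailed

#: residues weighted roughly like vertebrate protein composition, no K/R
#: internally (cleavage-like sequences end in K or R)
_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWY"))
_RESIDUE_W = np.array(
    [8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 9.7, 2.4, 4.1, 4.7, 4.0, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_RESIDUE_W = _RESIDUE_W / _RESIDUE_W.sum()


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-component random stream derived from the study seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SimulationDesign:
    """Cohort layout and measurement depth of a simulated study."""

    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (2, 5)
    n_animals_per_arm: int = 4
    arms: tuple[str, ...] = ("Con", "CR")
    days: tuple[float, ...] = (0, 9, 14, 20, 25, 27, 28, 29, 30, 31, 32, 40, 42, 73, 170)
    p_body: float = 0.05
    t_label: float = 4.0
    ion_counts: int | None = 10_000  # None = analytic (noise-free) envelopes
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_animals_per_arm < 1 or not self.arms:
            raise ValueError("counts must be positive and arms non-empty")
        if self.peptides_per_protein[0] < 1 or self.peptides_per_protein[0] > self.peptides_per_protein[1]:
            raise ValueError("invalid peptides_per_protein range")

    @property
    def context(self) -> LabelingContext:
        return LabelingContext(p_body=self.p_body, t_label=self.t_label)


@dataclass(frozen=True)
class EffectModel:
    """True-FSR structure: baseline distribution and arm/day effects.

    Baseline per-protein FSRs (fraction of pool renewed over the labeling
    window) are log-normal.  The calorie-restriction arm multiplies FSRs by
    a logistic ramp from 1 down to ``cr_multiplier_late`` centered at
    ``transition_day``; the NO-deficient arm raises FSRs by
    ``no_multiplier``; the combined arm gets both factors, attenuating the
    restriction effect.  Animal-level biological variation is log-normal.
    """

    baseline_log_mean: float = np.log(0.35)
    baseline_log_sd: float = 0.45
    cr_multiplier_late: float = 0.7
    transition_day: float = 27.5
    transition_steepness: float = 0.8
    no_multiplier: float = 1.3
    animal_jitter_sd: float = 0.10

    def cr_multiplier(self, day: float | np.ndarray) -> np.ndarray:
        ramp = 1.0 / (1.0 + np.exp(-(np.asarray(day, float) - self.transition_day) / self.transition_steepness))
        return 1.0 - (1.0 - self.cr_multiplier_late) * ramp

    def arm_multiplier(self, arm: str, day: float | np.ndarray) -> np.ndarray:
        if arm == "Con":
            return np.ones_like(np.asarray(day, float))
        if arm == "CR":
            return self.cr_multiplier(day)
        if arm == "NO-":
            return self.no_multiplier * np.ones_like(np.asarray(day, float))
        if arm == "NO-CR":
            return self.no_multiplier * self.cr_multiplier(day)
        raise ValueError(f"unknown arm {arm!r}")


def true_fsr_model(design: SimulationDesign, effects: EffectModel | None = None) -> pd.DataFrame:
    """Ground-truth protein FSR per (protein, arm, day, animal).

    True FSRs are clipped to [1e-4, 0.98]: a fraction of a pool renewed
    cannot leave (0, 1).
    """
    effects = effects or EffectModel()
    rng = component_rng(design.seed, "true_fsr")
    baseline = np.exp(rng.normal(effects.baseline_log_mean, effects.baseline_log_sd, design.n_proteins))
    proteins = np.array([f"P{i:05d}" for i in range(design.n_proteins)])
    rows = []
    for arm in design.arms:
        for day in design.days:
            mult = float(effects.arm_multiplier(arm, day))
            for animal in range(1, design.n_animals_per_arm + 1):
                jitter = np.exp(rng.normal(0.0, effects.animal_jitter_sd, design.n_proteins))
                fsr = np.clip(baseline * mult * jitter, 1e-4, 0.98)
                rows.append(
                    pd.DataFrame(
                        {
                            "protein_id": proteins,
                            "arm": arm,
                            "day": day,
                            "animal": animal,
                            "sample_id": f"{arm}_d{day:g}_a{animal}",
                            "fsr_true": fsr,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def _random_tryptic_sequence(rng: np.random.Generator, min_len: int = 7, max_len: int = 18) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    body = rng.choice(_RESIDUES, size=length - 1, p=_RESIDUE_W)
    terminal = "K" if rng.random() < 0.5 else "R"
    return "".join(body) + terminal


def draw_peptides(design: SimulationDesign) -> pd.DataFrame:
    """Assign each protein a set of distinct tryptic-like peptide sequences."""
    rng = component_rng(design.seed, "peptides")
    lo, hi = design.peptides_per_protein
    rows = []
    seen: set[str] = set()
    for i in range(design.n_proteins):
        n_pep = int(rng.integers(lo, hi + 1))
        for _ in range(n_pep):
            seq = _random_tryptic_sequence(rng)
            while seq in seen:
                seq = _random_tryptic_sequence(rng)
            seen.add(seq)
            rows.append({"protein_id": f"P{i:05d}", "sequence": seq})
    return pd.DataFrame(rows)


def simulate_peptide_envelopes(
    truth: pd.DataFrame,
    design: SimulationDesign,
    peptides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Measured-style peptide envelope table for every sample in ``truth``.

    Each peptide's M0-M3 envelope is the exact mixture
    (1-f)*baseline + f*asymptote in truncated isotopomer space at the true
    FSR of its protein in that sample; with ``ion_counts`` set, the envelope
    is re-drawn from a multinomial of that depth (ion-counting shot noise)
    and renormalized.  Spectral counts are geometric (support >= 1).
    """
    peptides = peptides if peptides is not None else draw_peptides(design)
    rng = component_rng(design.seed, "envelopes")
    ctx = design.context

    env_pairs = {}
    for seq in peptides["sequence"].unique():
        comp = composition_from_sequence(seq)
        n = exchangeable_site_count(seq)
        b, a = baseline_and_asymptote(comp, n, ctx, k_max=3)
        env_pairs[seq] = (b.abundances, a.abundances)

    merged = truth.merge(peptides, on="protein_id")
    if design.dropout_rate:
        keep = rng.random(len(merged)) >= design.dropout_rate
        merged = merged.loc[keep].reset_index(drop=True)
    rows = []
    for seq, f in zip(merged["sequence"], merged["fsr_true"].to_numpy()):
        b, a = env_pairs[seq]
        env = (1.0 - f) * b + f * a
        if design.ion_counts is not None:
            counts = rng.multinomial(design.ion_counts, env)
            env = counts / counts.sum()
        rows.append(env)
    out = merged[["sequence", "protein_id", "sample_id"]].copy()
    env_arr = np.vstack(rows)
    out[["m0", "m1", "m2", "m3"]] = env_arr
    out["spectral_count"] = rng.geometric(0.4, size=len(out))
    out["charge"] = rng.integers(2, 4, size=len(out))
    return out.reset_index(drop=True)


def study_metadata(truth: pd.DataFrame, design: SimulationDesign) -> pd.DataFrame:
    """Sample metadata table (sample_id, animal, group, day, p_body)."""
    meta = (
        truth[["sample_id", "animal", "arm", "day"]]
        .drop_duplicates()
        .rename(columns={"arm": "group"})
        .reset_index(drop=True)
    )
    meta["p_body"] = design.p_body
    return meta


def simulate_transcript_table(
    flux_table: pd.DataFrame,
    concordance_prob: float,
    seed: int,
    log2fc_sd: float = 1.0,
) -> pd.DataFrame:
    """Gene-level DE-style table whose directions track protein FSR changes.

    ``flux_table`` needs protein_id and log2fc.  Each gene's mRNA direction
    equals the protein's FSR direction with probability ``concordance_prob``,
    otherwise it is flipped; magnitudes are |N(0, log2fc_sd)|.
    """
    if not 0.0 <= concordance_prob <= 1.0:
        raise ValueError("concordance_prob must be in [0, 1]")
    rng = component_rng(seed, "transcripts")
    signs = np.sign(flux_table["log2fc"].to_numpy())
    agree = rng.random(len(signs)) < concordance_prob
    mrna_signs = np.where(agree, signs, -signs)
    mags = np.abs(rng.normal(0.0, log2fc_sd, len(signs)))
    mags = np.maximum(mags, 1e-6)  # zero FC carries no direction
    return pd.DataFrame(
        {"gene_id": flux_table["protein_id"].to_numpy(), "log2fc": mrna_signs * mags}
    )


def simulate_palmitate(
    design: SimulationDesign,
    f_dnl_by_arm: dict[str, float],
    species: LipidSpecies = PALMITATE,
) -> pd.DataFrame:
    """Palmitate envelope table per animal with known true DNL fractions."""
    rng = component_rng(design.seed, "palmitate")
    ctx = design.context
    b, a = baseline_and_asymptote(species.composition, species.n_sites, ctx, k_max=3)
    rows = []
    for arm, f in f_dnl_by_arm.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"true DNL fraction for {arm} outside [0, 1]")
        for animal in range(1, design.n_animals_per_arm + 1):
            env = (1.0 - f) * b.abundances + f * a.abundances
            if design.ion_counts is not None:
                counts = rng.multinomial(design.ion_counts, env)
                env = counts / counts.sum()
            rows.append(
                {
                    "sample_id": f"{arm}_a{animal}",
                    "group": arm,
                    "animal": animal,
                    "f_dnl_true": f,
                    "m0": env[0],
                    "m1": env[1],
                    "m2": env[2],
                    "m3": env[3],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    """A complete synthetic study: inputs for the pipeline plus ground truth."""

    design: SimulationDesign
    effects: EffectModel
    truth: pd.DataFrame
    peptides: pd.DataFrame
    metadata: pd.DataFrame
    peptide_map: pd.DataFrame = field(repr=False, default=None)


def simulate_study(
    design: SimulationDesign, effects: EffectModel | None = None
) -> SimulatedStudy:
    """Generate truth, peptide envelope table and metadata in one call."""
    effects = effects or EffectModel()
    truth = true_fsr_model(design, effects)
    pep_map = draw_peptides(design)
    peptides = simulate_peptide_envelopes(truth, design, pep_map)
    metadata = study_metadata(truth, design)
    return SimulatedStudy(
        design=design,
        effects=effects,
        truth=truth,
        peptides=peptides,
        metadata=metadata,
        peptide_map=pep_map,
    )


def null_binomial_pvalues(
    n_reps: int,
    seed: int,
    n_proteins: int = 200,
    n_animals: int = 4,
    effects: EffectModel | None = None,
    method: str = "double",
) -> np.ndarray:
    """Binomial p-values from repeated null (no-effect) proteome comparisons.

    Each replicate draws per-animal true FSRs for two identical arms from
    the effect model with every arm multiplier equal to 1, compares arm
    means per protein, and tests the resulting Up/Down split.  Used for
    type-I-error calibration of the sign test.
    """
    effects = effects or EffectModel()
    rng = component_rng(seed, "null_calibration")
    baseline = np.exp(
        rng.normal(effects.baseline_log_mean, effects.baseline_log_sd, (n_reps, n_proteins, 1))
    )
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        jitter = np.exp(rng.normal(0.0, effects.animal_jitter_sd, (n_proteins, 2 * n_animals)))
        fsr = baseline[r] * jitter
        mean_a = fsr[:, :n_animals].mean(axis=1)
        mean_b = fsr[:, n_animals:].mean(axis=1)
        diff = mean_b - mean_a
        n_down = int((diff < 0).sum())
        n_tot = int((diff != 0).sum())
        pvals[r] = binomial_two_tailed(n_down, n_tot, method=method)
    return pvals
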