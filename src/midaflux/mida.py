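"""Mass isotopomer distribution analysis (MIDA) for heavy-water labeling.

The model: during synthesis, ``n`` effective C-H positions of a peptide (or
lipid) equilibrate with body water, so each carries deuterium with the body
water 2H fraction ``p``; every other atom carries natural isotope abundances.
The molecule's isotopomer envelope is then the convolution of per-element
natural-abundance distributions with a binomial(n, p) site-labeling
distribution.  A partially renewed pool is a linear mixture of the unlabeled
(baseline, p = natural 2H) and fully renewed (asymptote, p = body water)
envelopes, so the fractional synthesis f follows from the depletion of the
monoisotopic peak M0:

    f = EM0 / EM0max = (M0_measured - M0_baseline) / (M0_asymptote - M0_baseline)

with all envelopes truncated to the M0..M3 window and renormalized first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import ElementalComposition
from .constants import NATURAL_2H, NATURAL_ABUNDANCE

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Normalized relative abundances of mass isotopomers M0..Mk."""

    abundances: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.abundances, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("envelope needs at least M0 and M1")
        if np.any(arr < -_NORM_TOL):
            raise ValueError("negative isotopomer abundance")
        total = arr.sum()
        if total <= 0:
            raise ValueError("all-zero envelope")
        object.__setattr__(self, "abundances", np.clip(arr, 0.0, None) / total)

    @property
    def k(self) -> int:
        return self.abundances.size - 1

    @property
    def m0(self) -> float:
        return float(self.abundances[0])


@dataclass(frozen=True)
class LabelingContext:
    """Body-water enrichment and labeling duration for one study."""

    p_body: float
    p_natural: float = NATURAL_2H
    t_label: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_natural < self.p_body < 1.0:
            raise ValueError(
                f"need 0 <= p_natural < p_body < 1, got {self.p_natural}, {self.p_body}"
            )
        if self.t_label <= 0:
            raise ValueError("labeling duration must be positive")


@dataclass
class PeptideMeasurement:
    """One measured peptide envelope with its identifications."""

    sequence: str
    protein_id: str
    sample_id: str
    measured_envelope: IsotopeEnvelope
    spectral_count: int = 1
    charge: int = 1  # metadata only; envelopes live in neutral isotopomer space

    def __post_init__(self) -> None:
        if not self.sequence or not self.sequence.isalpha() or not self.sequence.isupper():
            raise ValueError(f"invalid peptide sequence {self.sequence!r}")
        if self.spectral_count < 1 or self.charge < 1:
            raise ValueError("spectral_count and charge must be >= 1")


# QC bounds: estimates outside are flagged, never clipped
F_FLAG_LOW = -0.05
F_FLAG_HIGH = 1.2


@dataclass
class PeptideKinetics:
    """Fractional synthesis estimate for one peptide measurement."""

    em0: float
    em0_max: float
    f: float
    k_turnover: float | None = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.qc_flags


def _convolve_power(dist: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution by binary exponentiation."""
    result = np.array([1.0])
    base = np.asarray(dist, dtype=float)
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)
        base = np.convolve(base, base)
        n >>= 1
    return result


def _binomial_dist(n: int, p: float) -> np.ndarray:
    """pmf of Binomial(n, p) over 0..n (mass-shift distribution of n sites)."""
    k = np.arange(n + 1)
    log_pmf = (
        np.array([math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1) for i in k])
        + k * np.log(p if p > 0 else 1.0)
        + (n - k) * np.log1p(-p)
    )
    if p == 0:
        pmf = np.zeros(n + 1)
        pmf[0] = 1.0
        return pmf
    return np.exp(log_pmf)


def isotope_distribution(
    composition: ElementalComposition,
    n_labeled: int = 0,
    p_sites: float = NATURAL_2H,
    p_natural: float = NATURAL_2H,
) -> np.ndarray:
    """Full isotopomer mass-shift distribution of a molecule.

    ``n_labeled`` hydrogens carry 2H at probability ``p_sites``; the remaining
    hydrogens and all heavy atoms follow natural abundances.  Returns the
    untruncated probability vector indexed by nominal mass shift.
    """
    if n_labeled < 0 or n_labeled > composition.H:
        raise ValueError(f"n_labeled={n_labeled} outside [0, {composition.H}]")
    if not 0.0 <= p_sites < 1.0:
        raise ValueError("p_sites must be in [0, 1)")
    dist = np.array([1.0])
    for el, count in composition.as_dict().items():
        if count == 0:
            continue
        if el == "H":
            natural_h = np.array([1.0 - p_natural, p_natural])
            dist = np.convolve(dist, _convolve_power(natural_h, count - n_labeled))
            if n_labeled:
                dist = np.convolve(dist, _binomial_dist(n_labeled, p_sites))
        else:
            dist = np.convolve(dist, _convolve_power(NATURAL_ABUNDANCE[el], count))
    return dist


def truncate_and_renormalize(envelope: IsotopeEnvelope | np.ndarray, k: int = 3) -> IsotopeEnvelope:
    """Keep M0..Mk and rescale to unit sum.  Idempotent."""
    arr = envelope.abundances if isinstance(envelope, IsotopeEnvelope) else np.asarray(envelope, float)
    if arr.size < k + 1:
        raise ValueError(f"envelope has only {arr.size} peaks, need at least {k + 1}")
    window = arr[: k + 1]
    total = window.sum()
    if total <= 0:
        raise ValueError("truncation window sums to zero")
    return IsotopeEnvelope(window / total)


def theoretical_envelope(
    composition: ElementalComposition,
    n: float,
    p_sites: float,
    k_max: int = 3,
    p_natural: float = NATURAL_2H,
) -> IsotopeEnvelope:
    """Theoretical M0..Mk_max envelope with ``n`` labeled sites at ``p_sites``.

    Non-integer ``n`` is handled by linear interpolation between the full
    (untruncated) envelopes at floor(n) and ceil(n) before truncation, which
    keeps the closed-form M0 checks exact at integer n and the envelope
    continuous in n.
    """
    if n < 0 or n > composition.H:
        raise ValueError(f"n={n} exceeds the hydrogen count {composition.H}")
    lo, hi = int(math.floor(n)), int(math.ceil(n))
    dist = isotope_distribution(composition, lo, p_sites, p_natural)
    if hi != lo:
        w = n - lo
        dist_hi = isotope_distribution(composition, hi, p_sites, p_natural)
        size = max(dist.size, dist_hi.size)
        dist = np.pad(dist, (0, size - dist.size)) * (1 - w) + np.pad(
            dist_hi, (0, size - dist_hi.size)
        ) * w
    return truncate_and_renormalize(dist, k_max)


def baseline_and_asymptote(
    composition: ElementalComposition,
    n: float,
    context: LabelingContext,
    k_max: int = 3,
) -> tuple[IsotopeEnvelope, IsotopeEnvelope]:
    """Unlabeled baseline and fully renewed asymptote envelopes for a species."""
    baseline = theoretical_envelope(composition, n, context.p_natural, k_max, context.p_natural)
    asymptote = theoretical_envelope(composition, n, context.p_body, k_max, context.p_natural)
    return baseline, asymptote


def em0_excess_and_max(
    measured: IsotopeEnvelope,
    baseline: IsotopeEnvelope,
    asymptote: IsotopeEnvelope,
) -> tuple[float, float]:
    """Excess M0 of the measurement and its full-turnover asymptotic value."""
    if not measured.k == baseline.k == asymptote.k:
        raise ValueError("envelopes must share the same truncation window")
    em0 = measured.m0 - baseline.m0
    em0_max = asymptote.m0 - baseline.m0
    if em0_max == 0.0:
        raise ValueError("EM0max is zero: no kinetic information (n = 0 or no enrichment)")
    return em0, em0_max


def fractional_synthesis(
    em0: float,
    em0_max: float,
    t_label: float | None = None,
    compute_rate: bool = False,
) -> PeptideKinetics:
    """Fractional synthesis f = EM0/EM0max, with optional first-order rate.

    The measurement is modeled as (1-f)*baseline + f*asymptote, making f exact
    for noise-free mixtures.  Estimates outside [0, 1] are kept but flagged
    (bounds -0.05 / 1.2) rather than clipped, so group means stay unbiased.
    """
    if em0_max == 0.0:
        raise ValueError("EM0max is zero: fractional synthesis undefined")
    f = em0 / em0_max
    flags: list[str] = []
    if f < F_FLAG_LOW:
        flags.append("f_below_lower_bound")
    elif f > F_FLAG_HIGH:
        flags.append("f_above_upper_bound")
    k_turnover = None
    if compute_rate:
        if t_label is None or t_label <= 0:
            raise ValueError("compute_rate requires a positive labeling duration")
        if 0.0 <= f < 1.0:
            k_turnover = -math.log1p(-f) / t_label
        else:
            flags.append("rate_unresolvable")
    return PeptideKinetics(em0=em0, em0_max=em0_max, f=f, k_turnover=k_turnover, qc_flags=flags)
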