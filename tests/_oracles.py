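"""Independent oracles used by the test suite.

These deliberately avoid the package's convolution/scipy code paths:
envelope probabilities come from direct enumeration of isotope-count
combinations with exact multinomial coefficients, and the exact tests come
from exhaustive outcome enumeration with rational arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial

# natural abundances restated independently (same physical constants)
ABUNDANCES = {
    "H": [(0, 0.999885), (1, 0.000115)],
    "C": [(0, 0.9893), (1, 0.0107)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
}


def _atom_group_terms(isotopes, m, k_max):
    """All (shift, prob) terms for m identical atoms, total shift <= k_max.

    Enumerates how many of the m atoms carry each heavy isotope and weights
    by the exact multinomial coefficient.
    """
    shifts = [s for s, _ in isotopes]
    probs = [p for _, p in isotopes]
    heavy = list(range(1, len(isotopes)))
    terms = []
    # counts per heavy isotope; bounded by the shift budget
    ranges = [range(0, min(m, k_max // shifts[i]) + 1) for i in heavy]
    for combo in itertools.product(*ranges):
        n_heavy = sum(combo)
        shift = sum(c * shifts[i] for c, i in zip(combo, heavy))
        if n_heavy > m or shift > k_max:
            continue
        coeff = factorial(m)
        for c in combo:
            coeff //= factorial(c)
        coeff //= factorial(m - n_heavy)
        prob = coeff * probs[0] ** (m - n_heavy)
        for c, i in zip(combo, heavy):
            prob *= probs[i] ** c
        terms.append((shift, prob))
    return terms


def envelope_window_oracle(composition, n_labeled=0, p_sites=0.000115,
                           p_natural=0.000115, k_max=3):
    """Unnormalized M0..Mk_max abundances by direct enumeration.

    ``composition`` is a mapping element -> atom count.  ``n_labeled``
    hydrogens carry 2H at probability ``p_sites``; everything else is at
    natural abundance.
    """
    groups = []
    for el, m in composition.items():
        if m == 0:
            continue
        if el == "H":
            m_nat = m - n_labeled
            if m_nat:
                groups.append(_atom_group_terms([(0, 1 - p_natural), (1, p_natural)], m_nat, k_max))
            if n_labeled:
                groups.append(_atom_group_terms([(0, 1 - p_sites), (1, p_sites)], n_labeled, k_max))
        else:
            groups.append(_atom_group_terms(ABUNDANCES[el], m, k_max))
    window = [0.0] * (k_max + 1)
    for combo in itertools.product(*groups):
        shift = sum(s for s, _ in combo)
        if shift > k_max:
            continue
        prob = 1.0
        for _, p in combo:
            prob *= p
        window[shift] += prob
    return window


def binomial_two_tailed_oracle(k, n):
    """Doubled-smaller-tail sign test by exhaustive 2^n outcome enumeration."""
    n_le = n_ge = 0
    for outcome in itertools.product((0, 1), repeat=n):
        s = sum(outcome)
        if s <= k:
            n_le += 1
        if s >= k:
            n_ge += 1
    total = 2**n
    return min(1.0, 2.0 * min(Fraction(n_le, total), Fraction(n_ge, total)))


def fisher_two_tailed_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration (exact rationals).

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed the observed one (exact-tie inclusive).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    def point(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = point(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if point(x) <= p_obs:
            total += point(x)
    return float(total)
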