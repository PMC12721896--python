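# Methods

## Envelope model

A molecule's mass-isotopomer envelope is modeled in neutral isotopomer
space as the convolution of independent per-atom isotope distributions.
Natural abundances are fixed IUPAC representative values for H, C, N, O
and S (`midaflux/constants.py`); results depend only weakly on the exact
table, and it can be overridden along with every other constant.

During synthesis, an effective number *n* of C–H positions per residue
equilibrates with body water, so those hydrogens carry ²H with the
body-water fraction *p* instead of the natural fraction (1.15 × 10⁻⁴).
The per-residue effective site counts are real-valued because exchange is
partial; the shipped table (`data/exchangeable_sites.tsv`) holds
literature-derived in vivo values and is an explicit, replaceable input —
any re-analysis should state which table it used. Non-integer peptide
totals *n* are handled by linear interpolation between the full envelopes
at ⌊n⌋ and ⌈n⌉, which keeps the closed-form check
M0(p)/M0(nat) = ((1−p)/(1−p_nat))ⁿ exact at integers and the envelope
continuous in *n*.

All envelopes — measured, baseline (computed at natural abundance) and
asymptote (computed at the sample's body-water enrichment) — are truncated
to the M0–M3 window and renormalized before any EM0 arithmetic, because
M0–M3 is the assessed window in this kind of LC-MS work. The baseline is
theoretical by default; an empirical unlabeled-reference envelope can be
substituted per peptide by passing it in place of the computed one.

Fractional synthesis is read off M0 only: f = EM0/EM0max. The full-envelope
alternative (least-squares over M0–M3) was considered and not implemented,
since for a two-component mixture the M0 coordinate already determines f
exactly and the extra peaks add no identifiability in this model.
Estimates outside [0, 1] are kept and flagged (bounds −0.05 and 1.2)
rather than clipped; silent clipping would bias group means toward the
interior. An optional first-order rate k = −ln(1−f)/t is available for
f ∈ [0, 1).

## Rollup and group statistics

Peptide f values are aggregated to one protein FSR per animal by a
spectral-count-weighted mean (weighting approximates measurement
precision; unweighted mean and median are config switches). Protein
measurements with fewer than 2 peptide spectra in a sample are excluded;
the filter is per-sample by default with a study-wide switch, since either
reading of "per protein" is defensible. Group summaries use the sample SD
(n−1) and report CV = 100·SD/mean, defined only for ≥2 animals and
positive mean.

The stringency cutoff for calling a fold change meaningful is the
unweighted average of all defined per-protein CVs pooled over both arms
being compared, and the comparison is |percent change of FSR| > threshold,
both on the percent scale. Two-tailed binomial p-values use the
doubled-smaller-tail convention (capped at 1) to match the coin-toss
framing; the minimum-likelihood convention is available via
`method="minlike"`. Fisher's exact test contrasts (Down, Up) counts
between two arms. Exact ties (log₂FC = 0) are excluded from the sign test
and reported separately.

The time-course summary reports per-day percent-down (all proteins and
above-CV only) plus log₂ ratios to the reference day in both sign
conventions, because the figure-style −log₂ orientation is a presentation
choice. Transition detection — an addition beyond the descriptive
treatment such data usually gets — fits a 4-parameter logistic to
percent-down vs day (scipy `curve_fit`, midpoint bounded to the observed
day range) and reports its midpoint, alongside the first day exceeding a
configurable percent-down threshold (default 70%). A series whose
percent-down spans less than 2 percentage points is treated as flat: no
transition is reported.

WPASR multiplies each protein's FSR by its normalized label-free intensity
quotient Q (intensities divided by their within-sample sum). The WPASR
matrix normalization divides each sample by its median, log₁₀-transforms,
and mean-centers each protein row; non-positive intensities are masked,
not imputed.

Z-scores use the sample SD and are pooled across arms within a time point
by default (`pooled=False` standardizes within arm); the pooling choice is
exposed because either reading of "relative to the mean of the group" is
defensible.

## Lipogenesis

Palmitate (C₁₆H₃₂O₂) is treated by the identical mixture machinery with
n = 22 effective ²H-incorporating hydrogens, the field-standard effective
value for de novo synthesized palmitate; it is configurable because
published values vary with assumed precursor chemistry. Precursor
enrichment is the measured body-water p; estimating p from EM1/EM2 ratios
is out of scope.

## Concordance

mRNA direction is taken from the sign of a supplied log₂FC column — the
differential-expression model that produced it is upstream. No FDR filter
is applied by default; all matched gene–protein pairs enter the binomial
concordance test. Many-to-many gene–protein mappings are excluded with a
logged reason rather than arbitrarily resolved.

## Synthetic studies

The generator emulates the study design this analysis expects: arms
{Con, CR, NO⁻, NO-CR}, replicate animals (default 4 per arm, matching
typical n = 3–5 cohorts), body-water enrichment 0.05, a 4-day labeling
window, and the dense day grid 0–170 used for transition mapping.

True protein FSRs are log-normal across proteins (median 0.35 over the
labeling window, σ_log = 0.45 — a realistic center and spread for liver
proteins over four days, where much of the proteome turns over
substantially). The restriction effect is a logistic ramp in day from
multiplier 1 to 0.7, midpoint 27.5 d and steepness 0.8 d: the functional
form and midpoint encode a rapid transition bracketed between days 25 and
30, and the 0.7× late effect size is a documented free choice that
reproduces the observed prevalence pattern (~50% of proteins called Down
before the transition, >70% after) without being a fitted quantity. The
NO-deficient arm multiplies FSRs by 1.3; the combined arm gets both
factors, i.e. an attenuated net slowdown. Animal-level biological
variation is log-normal (σ = 0.10). True FSRs are clipped to
[10⁻⁴, 0.98] since a renewed fraction cannot leave (0, 1).

Peptides are random tryptic-like sequences (length 7–18, vertebrate-like
residue frequencies, C-terminal K/R). Each measured envelope is the exact
truncated-space mixture at the protein's true FSR; measurement noise is a
multinomial draw of default depth 10⁴ ions, renormalized — because the
mixture is formed after truncation and the multinomial is unbiased per
bin, the M0-based estimator is unbiased by construction, which the
recovery tests confirm (bias ≪ 0.005, RMSE ≈ 0.011 at that depth).
Spectral counts are geometric (p = 0.4, support ≥ 1); optional peptide
dropout is Bernoulli. All randomness derives from one integer seed through
CRC-named generator streams, so every table is bit-reproducible.

What the simulator does not model: chromatographic interference,
charge-state-dependent envelope distortion, peptide misidentification,
shared peptides between proteins, missing-value mechanisms beyond uniform
dropout, and day-dependent body-water enrichment drift. Passing tests
therefore demonstrate correctness of the estimator and statistics under
the stated noise model, not robustness to those instrument-level
artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 200–300 proteins,
2–5 peptides per protein, 4 animals per arm and up to 12 study days —
small enough to re-run anywhere in minutes while keeping the binomial
percent-down estimates at the few-percent precision the pattern checks
need. Envelope truncation tolerance is exact renormalization (sum 1 within
10⁻¹²); degenerate inputs (all-zero envelopes, zero EM0max, constant
z-score input, all-masked WPASR samples) raise errors naming the problem
rather than returning NaNs.
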