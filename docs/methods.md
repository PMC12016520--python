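# Methods

This note records the models implemented in bpiso, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written
down.

## The measurement chain being modelled

Compound-specific δ²H of biphytanes is measured by GC-pyrolysis-IRMS
against an H₂ working gas. Three systematic effects separate a raw
value from a VSMOW-scale value: a constant offset (working-gas
calibration), a scale compression (the measured range is slightly
narrower than the true range), and a peak-size or linearity effect
(measured ratio depends weakly on signal amplitude). Upstream of the
instrument, the chemistry itself perturbs the signal: releasing
biphytanes from iGDGTs cleaves two ether bonds and the subsequent
hydrogenation adds hydrogen atoms whose isotopic composition is not the
lipid's.

### Calibration

The standards regression is fitted in the *inverted* orientation —
raw value as response on accepted value:

    d2H_raw = β0 + β1·accepted + β2·A + β3·accepted·A + e

and solved for `accepted` per unknown peak. This is the standard
errors-in-calibration arrangement: the noisy quantity is the response,
so OLS assumptions hold, and inversion at prediction time transfers the
unknowns onto the accepted scale. The amplitude covariate is peak
amplitude by default (area selectable at the I/O level since both are
carried); the interaction term β3 is off by default — with typical
standards designs it is weakly identified and the linear size term
absorbs most of the effect. The exact covariate structure used by any
given lab's processing chain varies; the terms here are toggleable and
every fit logs which were used.

Per-peak 1σ has two components, combined in quadrature:
(1) the delta-method prediction variance from the coefficient
covariance, and (2) a repeatability floor estimated from the standards'
own residuals, binned by amplitude quantile and summarized by the
fitted law σ(A) = a + b/A (a, b ≥ 0). Fitting the law through the bins,
rather than using the raw bin RMS values, guarantees the physically
expected monotone behaviour: calibrated σ never increases with peak
size. If the two-parameter fit degenerates (negative coefficients), a
flat floor equal to the pooled RMS is used instead.

Outlier standards are never dropped by default. An optional robust
refit removes peaks with |studentized residual| > 4 and refits once,
logging what was dropped.

### Hydrogenation correction

Ether cleavage plus hydrogenation leaves a biphytane (C₄₀H₈₂) carrying
two hydrogens that were added chemically, one at each cleaved terminus.
The measured molecule is a two-pool mixture, so the biosynthetic value
is recovered by mass balance:

    δ_corr = (n_total·δ_meas − n_added·δ_added) / (n_total − n_added)

with defaults n_total = 82, n_added = 2 (both configurable — some
derivatization schemes add more H). σ propagates with the same weights
in quadrature. With the synthetic generator's default
δ_added = −720‰, the correction lands at +10–13‰ for typical biphytane
values — the magnitude reported for real reductions — and inflates σ by
well under 2‰. The δ²H of the added hydrogen is treated as a free
parameter throughout: it depends on the H₂/PtO₂ batch and must be
supplied (or calibrated) by the lab.

## Fractionation algebra and aggregation rules

- ²ε_L/W = ((1000 + δ_BP)/(1000 + δ_W) − 1)·1000. ε is computed per
  culture from that culture's own δ_BP and δ_W, and cultures are then
  combined per treatment by weighted mean — not ε of the mean deltas.
  The two orders differ at the ≤1‰ level when waters differ between
  replicates; the per-replicate order is the physically meaningful one
  and is logged.
- Weighted means use 1/σ² weights. The reported σ is the larger of the
  weighted replicate SD (with an effective-n bias correction) and the
  propagated standard error of the mean — conservative when replicate
  scatter exceeds what the per-measurement σ predicts. A σ floor
  (default 0.5‰, the media-water analytical precision scale) replaces
  zero σ so noise-free synthetic data and zero-variance replicate sets
  stay well posed.
- Abundance-weighted means include only moieties with relative
  abundance > 5% *evaluated over all detected moieties*; surviving
  abundances are renormalized; excluded moieties are warned about.
  Abundance uncertainty is not propagated (weights are treated as
  fixed).
- Δε/ring(X) is the unweighted mean over all lower-ring partners Y of
  (ε_X − ε_Y)/(X − Y); BP-0 is 0 by definition; "n.d." moieties join
  neither pairs nor means.
- The single-number treatment summary ("mean ring difference") is the
  unweighted OLS slope of per-moiety ε on ring number. This choice was
  reverse-verified cell-by-cell against the bundled study's printed
  summary column (e.g. the three chemostat treatments give slopes
  9.1, 7.9, 5.0 → printed 9, 8, 5, mean 7.3 ≈ the reported 7.4‰/ring
  per-ring enrichment); an abundance-weighted mean of the per-moiety
  Δε/ring values does not reproduce those cells.
- Ring indices normalize internally by the abundance sum, so they are
  invariant to rescaling (raw areas work as well as fractions).

## Growth kinetics

μ is the OLS slope of ln(OD₆₀₀) on time over the window where OD lies
between 5% and 60% of the curve's maximum — a quantified stand-in for
"early to mid-exponential phase", configurable and reported with every
fit. T_D = ln 2/μ. Chemostats bypass the fit entirely: at steady state
the doubling time *is* the set dilution time, and the bundled study's
chemostat rows illustrate why the fit would mislead (printed μ values
there are not ln 2/T_D; the package flags the source of every T_D it
reports rather than reconciling them).

## Study statistics

Condition regressions are OLS with a two-sided t-test on the slope,
fitted on treatment means by default (what study figures display);
replicate-level fitting is a caller choice. Correlation matrices are
pairwise Pearson r with raw two-sided p values starred at
0.05/0.001/0.0001 — no multiple-testing correction by default, matching
the reporting convention the bundled study uses (a Benjamini–Hochberg
adjustment can be applied downstream from the tidy output). Bartlett's
K² comes from scipy; the test suite pins it against an independently
written textbook formula. The water-H mass balance is a two-endmember
linear mixing model, δ_L = f·(δ_W + ε_w) + (1−f)·(δ_S + ε_s), solved
for f with first-order σ; the path fractionations are mandatory
arguments because they are assumptions, not observables, and a
lower-bound mode sets ε_s = 0 (any real negative substrate-path
fractionation would raise f, so the solved value is a floor).

## The synthetic generator

Defaults encode the study conditions the reduction targets: 5
treatments × 3 replicates; true ²ε_L/W drawn per culture from
N(−204‰, 12‰); +7.4‰ per cyclopentane ring; media water uniform over
−61…−46‰; abundance 4-vectors from Dirichlet(13, 30, 49, 8) (matching
mean observed abundances of ~13/30/49/7% with realistic scatter);
instrument offset +20‰, scale 0.97, size effect 0.002‰/mV; noise
σ(A) = 2‰ + 2000‰·mV/A, i.e. ~2.3‰ on a large peak and ~4.5‰ on a
small one; three injections per sample; standards ladders co-run per
culture at randomized amplitudes. The n-alkane ladder spans −263…−9‰
plus nC36 at −259.2‰; the individual ladder values are synthetic,
evenly spaced over that span.

The generator starts at the integrated-peak level. It does not emulate:
chromatographic co-elution or peak detection, H₃⁺-factor drift, memory
effects between injections, within-run calibration drift, correlated
errors between moieties of one injection, or abundance-dependent
detection limits (BP-3 is generated even when rare; real runs lose it).
Passing tests therefore demonstrate the *reduction* is correct under
the stated error model, not that the error model exhausts real
instrument behaviour.

Truth tables travel on a separate attribute and file
(`truth.tsv`) so reduction code cannot consume them by accident. All
randomness flows from one explicit seed through per-culture child
generators; fixed seed ⇒ identical datasets.

## Numerical choices and degenerate inputs

- Calibration inversion refuses |effective scale| < 1e-8; rank-deficient
  standards designs and unmapped compounds fail with named errors.
- δ values at or below −1000‰ (unphysical) are rejected in ε algebra.
- Empty weighted means, all-zero abundance vectors, sub-3-point growth
  windows, constant-x regressions, and zero-variance Bartlett groups
  are errors, not NaNs; zero-variance correlation columns are reported
  as undefined rather than erroring, so one flat column does not kill a
  matrix.
- Rendered reports round δ/ε to integers and RI/abundances to two
  decimals (display convention); TSV outputs keep full precision, and
  every reported number exists as a table cell.

## Problem sizes used in validation

The statistical checks run at sizes chosen to bound their Monte-Carlo
error well below the tolerances they assert: 1000 replicate standards
runs for the noise-law check (±10%), 1000 peaks for 2σ coverage
(≥93%), 1000–2000 null replicates for type-I error calibration of the
slope and Bartlett tests (5% ± 2%), and 20 treatments for the
end-to-end recovery distribution. The full suite completes in well
under a minute on one core.

## Known limitations

- The calibration covariate structure is a declared default, not a
  reconstruction of any specific lab's processing software.
- Abundance weights carry no uncertainty; for samples where a moiety
  sits near the 5% threshold, the weighted mean's σ is optimistic.
- The mixing model is two-endmember and linear; real H flux through
  NADPH-mediated biosynthesis need not be.
- Treatment-level aggregation assumes replicate cultures are
  exchangeable; batch effects between runs are not modelled beyond the
  shared calibration.
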