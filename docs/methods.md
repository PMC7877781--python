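# Methods

## Predator-vision model

The spider's color perception is modeled with a single green-sensitive
photopigment.  Its normalized absorbance is the Govardovskii α-band template
for an A1 (retinal) chromophore,

    S(λ) = 1 / [exp(A(a−x)) + exp(B(b−x)) + exp(C(c−x)) + D],   x = λmax/λ,

with A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922, c = 1.104 and the
peak-dependent a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940).  Only the α band
is used; the β band (a secondary short-wavelength shoulder) is omitted
because the analysis is confined to the visible grid, where its contribution
at λmax = 520 nm is negligible.  The template is exact to the formula: on a
0.1 nm grid its maximum is 1.0008 at 520.0 nm, inside the documented
[0.99, 1.02] normalization band.  The model deliberately has no UV channel,
no receptor noise, and no illuminant term — it asks only how much reflected
light one pigment can absorb, not what a full color-vision model would
discriminate.

The *green component* of a cuticle patch is the pointwise product
R(λ)·S(λ) of measured reflectance and template, integrated by the composite
trapezoidal rule on the analysis grid (default 400–700 nm, 1 nm step;
configurable).  Halving the step changes areas by well under 0.5% for smooth
spectra, so the default grid is not a limiting approximation.  Reflectance
input may be percent- or fraction-scaled; files whose maximum exceeds 1.5
are treated as percent and divided by 100 (an explicit `units=` override
exists).  Interpolation onto the analysis grid is linear and refuses to
extrapolate beyond the measured span.

The absorption contrast of a genus is mean black-patch area minus mean
orange-patch area.  Replicate spread enters as the sample SD (n−1) of the
per-replicate areas, and the contrast error is the independent-quadrature
sum √(SD²_black + SD²_orange); contrasts with |value| ≤ error are flagged
`within_error`, i.e. indistinguishable patches given measurement spread.
Quadrature assumes the two patch measurements are independent, which holds
for separately measured cuticle regions.

## Behavioral model

Raw behavior codes 1–7 collapse to detect (1–2), attack (3–4), avoid (5–6);
code 7 ("None") has no grouped meaning and is excluded from grouped
analyses.  A trial's response is its modal grouped action; ties break by
escalation precedence attack > avoid > detect, chosen so that the rarer,
more consequential outcome is preserved (the alternative — first occurrence
— would make the response depend on event ordering noise).  Trials whose
events are all code 7 have no defined response and raise rather than being
silently dropped.

The multinomial logistic regression uses attack as the reference category,
so coefficients read directly as detect-versus-attack and
avoid-versus-attack log-odds.  Continuous covariates (wasp and spider length
in mm) are standardized to mean 0, SD 1 before fitting; categorical
covariates are dummy-coded against the alphabetically first level.  Fitting
is Newton-Raphson maximum likelihood (statsmodels MNLogit) with tolerance
1e-10 and up to 200 iterations, falling back to BFGS; non-convergence
(e.g. perfect separation) is flagged on the fit and surfaced as a warning,
never hidden.  Rank-deficient designs are rejected with the collinear
columns named.  Model comparison uses AIC = 2k − 2ℓ with ties broken toward
fewer parameters, then listed order.  Percentage summaries use per-genus
denominators for BOB trials but pool black trials across genera — black
cuticle is spectrally alike between genera, so the pooled denominator is the
better-powered estimate.

## Contingency analysis

The G statistic is 2·Σ O·ln(O/E) with E from the row/column margins, zero
cells contributing 0 (the x·ln x → 0 limit), compared to chi-square with
(r−1)(c−1) df.  No small-sample correction is applied by default — the
shipped 30-trial tables reproduce their published statistics exactly under
the uncorrected formula — but the Williams correction is available as an
option.  Expected counts below 5 trigger a warning; all-zero rows or columns
are dropped with a df reduction and flag.  Pearson's X² is provided as an
asymptotically equivalent cross-check, and the test's empirical size is
verified by simulation (about 5% at α = 0.05 for n = 200 tables).

## Dose-response model

The two-parameter log-logistic p(d) = 1/(1 + exp(b·(ln d − ln e))) has lower
asymptote 0 and upper asymptote 1: control mortality is assumed absent (as
observed in the assays), so no Abbott correction is applied.  Binary
endpoints are fitted by binomial maximum likelihood via a logistic GLM on
ln(dilution) — the identical model in GLM parameterization, with
ln e = −β₀/β₁ — and continuous inhibition fractions by least squares on the
same mean function.  The 95% CI is a normal approximation on ln e via the
delta method from the fit covariance; a profile-likelihood CI would be
slightly asymmetric but agrees closely at these sample sizes.  Estimates
above the highest tested concentration (100% of the pure extract), and fits
to flat all-zero or all-saturated series, are reported as "> 100%" with no
point estimate.  Simulation at the assay design (dilutions 25/50/75/100%,
triplicates of 10 organisms) recovers a true LC50 of 60% with median error
under a few percent, and the CI covers the truth in ≥ 88% of runs — mild
undercoverage expected from the delta method at 12 binomial observations.

## Synthetic data

The generators reproduce the statistical *structure* of each input family,
not any measured dataset:

* **Spectra** — orange cuticle is a long-pass sigmoid (defaults: edge
  560 nm, width 15 nm, rising from 0.04 to 0.45 reflectance) and black
  cuticle is flat at 0.04, both times a per-replicate lognormal factor
  (σ = 0.10, i.e. ~10% multiplicative replicate noise, a typical
  between-specimen spread for cuticle spectrophotometry); 5 replicates per
  patch.  The edge/low-reflectance choices qualitatively match measured BOB
  cuticle shapes and place strong orange reflectance through the 480–560 nm
  flank of the 520 nm pigment, so the generated contrast is negative —
  the construction used by the sign tests.
* **Trials** — spider types are drawn 68:51:17 (the study composition for
  its 136 trials), wasp color 50:50, genus uniform; the modal action comes
  from a per-(type, color) probability vector (defaults encode
  BOB-shifts-mass-from-attack-to-detect/avoid, strongest in captive
  adults), and the event sequence (Poisson, mean 7 events — the study's 954
  actions over 136 trials) is constructed with a strict majority of events
  in the drawn category so the modal response equals the draw exactly.
* **False prey** — covariate levels drawn independently; P(same response)
  is constant (default 0.7, matching 21/30 same responses) or keyed to one
  covariate's levels to inject dependence.
* **Mortality** — binomial counts around the log-logistic mean at the assay
  design; defaults LC50 = 60%, slope −4 (a moderately steep curve placing
  the observed 25–100% dilutions across the informative range).

Every generator is a pure function of (model, seed); one global seed spawns
independent per-stage substreams.  What passing tests show is therefore that
the estimators recover the generating process under idealized assumptions
(independent trials, exact model form, no measurement drift); they cannot
show robustness to the field realities the generators omit — correlated
replicates, non-sigmoid cuticle spectra, observer misclassification, or
between-pool extract variability.

## Pipeline

The YAML-driven pipeline runs each stage independently: a missing input
skips its stage with a logged warning; a stage error is recorded in the
manifest and fails the run's exit status without aborting other stages.  The
manifest carries the config hash, SHA-256 input checksums, package version
and per-stage timing; numeric CSV output is written at 6 significant digits.

## Problem sizes in the checks

The simulation-based checks use 100 replicates of 2000 trials for AIC
selection, 200 replicates of the 4×3×10 mortality design for LC50 recovery,
500 replicates for CI coverage, and 2000 null tables for G-test calibration
— sizes at which the binomial/multinomial Monte-Carlo error is comfortably
below the asserted tolerances.

## Known limitations

* The absorption contrast is a single-channel absorbed-light difference, not
  a discriminability model; it cannot rank stimuli the way a receptor-noise
  chromatic distance would.
* Wald (delta-method) intervals and p-values are first-order; near-boundary
  dose-response fits (LC50 near the top dilution) can have poor interval
  geometry, which the censoring rule partly absorbs.
* The multinomial model treats trials as independent; spiders are used once
  each, but shared session/arena effects are not modeled.
* AIC selection among a small candidate list is not a search over all
  covariate subsets.
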