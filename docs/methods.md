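# Methods

This note records the statistical models, the numerical choices behind
their implementation, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the problem left room.

## Occupancy model

The single-season occupancy likelihood treats each site's occupancy
state as a latent Bernoulli(ψ_i) variable and each survey, conditional
on occupancy, as an independent Bernoulli(p_ij) detection.  Both
parameters use logit links; occupancy covariates must be site-level,
detection covariates may be site- or survey-level (site-level columns
broadcast across occasions).  Sites with some surveys missing contribute
only their observed occasions; a site with all occasions missing would
contribute a likelihood factor of one and is rejected at construction
instead.  The "occupied sites" (OS) variant fixes ψ ≡ 1 and drops the β
block entirely, leaving a product-Bernoulli detection likelihood — the
right model when the analysis is restricted to sites where presence is
already established.

Key assumptions: closed occupancy state across occasions, independent
surveys given the state, no false positives, and no unmodelled
heterogeneity in p beyond the covariates supplied.

## Abundance model

Repeated counts are modelled as binomial thinning of a latent abundance
N_i with a zero-inflated Poisson state distribution: P(0) = φ + (1−φ)e^{−λ},
P(n>0) = (1−φ)·Poisson(n; λ), log link on λ, logit on detection, and a
single φ shared across sites (no covariates on the zero-inflation; the
data that motivated the model give no reason for site-varying excess
zeros).  The latent sum is truncated at K_max, default max observed
count + 100.  After fitting, the optimum is re-evaluated at a doubled
bound; a change above 1e-6 triggers a refit at the larger bound, so the
reported likelihood is insensitive to truncation.  A user-fixed K_max
that truncates non-negligible mass raises rather than silently biasing
λ̂ — with low individual detection the posterior over N reaches several
times the largest count, which is exactly the regime where a
"max count + small constant" bound fails.

Expected site abundance is the ZIP mean (1−φ)λ_i; divided by a
user-supplied stream-volume proxy (m³ per km of stream; fixtures draw
volumes uniformly from the plausible 715–12,956 m³/km range) it gives a
density in turtles/m³/km.  Densities for sites outside the fitted subset
(e.g. sites occupied only per eDNA) are covariate-based predictions from
the same models, flagged by the `fitted` column of the density table —
the only defensible source when no counts exist for those sites.

## Model selection and averaging

The two-stage screen first evaluates all observation-covariate subsets
of size ≤ 3 with the state model held constant (occupancy fixed to one
on detected sites, or intercept-only abundance), then carries the best
stage-one observation set, fixed, into a second stage crossing all
site-covariate subsets of size ≤ 2.  Intercept-only models are always
included.  "Influential" observation covariates are those in the
stage-one AICc-best model.

Ranking uses AICc with the number of sites as the effective sample size
(this reproduces the published model-table arithmetic at n = 37 and
n = 20).  Akaike weights are computed over the full candidate set, not
the printed top set.  Ties are broken by smaller K, then model name, so
ordering is total and deterministic.  When a stage is run on fewer sites
than parameters + 1 (degenerate designs, e.g. a single occupied site)
AICc is undefined; those rows carry plain AIC and a warning rather than
an error, since the small-n flag — not a crash — is the useful output.

Averaging happens on the link scale: the averaged linear predictor is
Σ w_m η_m, and the unconditional standard error is
Σ w_m sqrt(var_m + (η_m − η̄)²), back-transformed afterwards so
estimates and interval endpoints stay in range.  Unconverged models are
excluded with weight renormalization and a warning.

## Optimization and uncertainty

All fits use BFGS from deterministic multistart points (zeros — or a
count-informed abundance intercept — plus ±1 perturbations of the block
intercepts; five starts by default, reducible to one for large
simulation studies where the likelihood is well-behaved), gradient
tolerance 1e-8 by default.  The coefficient covariance is the inverse of
the numerically differentiated observed information
(`statsmodels.tools.numdiff.approx_hess1`); when the information matrix
is singular or any coefficient exceeds 10 on the link scale (a boundary
estimate, e.g. every site detected), the fit is flagged and intervals
are reported as unavailable rather than fabricated.  Intervals elsewhere
are delta-method on the link scale with a configurable multiplier z
(default 1.96); z = 1 bands are labelled ±1 SE, which is what the
published naive-occupancy "CIs" turn out to be.

## Agreement statistics

The g-test of independence is G = 2 Σ O ln(O/E) with margin-based
expected counts, (r−1)(c−1) degrees of freedom, chi-square p-value, no
continuity correction; zero cells contribute nothing.  On the 2×2
VES × eDNA site cross-classification reconstructed from the reported
tallies (13 both, 4 VES-only, 3 eDNA-only, 17 neither) this gives
G ≈ 15.2 with df = 1 — strong agreement between methods.  The original
report prints "G = 0.60007, df = 36, p = 1.0" for this comparison, which
does not follow from any standard contingency-table computation we can
reconstruct (df = 36 suggests some per-site decomposition that is not
described); the implementation therefore validates against a brute-force
expected-count oracle and the Pearson chi-square large-count limit, and
the printed statistic is documented here as irreproducible rather than
targeted.

Naive occupancy intervals are Wald p̂ ± z·sqrt(p̂(1−p̂)/n) truncated to
[0, 1].  With z = 1 they reproduce the published naive bands — except
the 16/37 lower bound, which computes to 0.351 against a printed 0.36;
we treat that printed digit as a rounding slip and compare within one
unit of the last printed decimal.

## Cost model

Costs are line items (unit cost × product of multipliers) classified as
startup (equipment, training) or recurring, with a 33% overhead applied
once to designated laboratory items (supplies and technician time).
Amortization divides the per-study total by sites and by samples per
site; defaults are a 40-site design with 2 VES surveys or 6 eDNA filters
(4 samples + 2 field blanks) per site.  The default ledgers reproduce
the published cost table's internally consistent cells; two printed
cells in that table (the eDNA field subtotal and the VES with-startup
per-site cost) disagree with their own line items and are not
reproduced.  Reports round to 0.1 USD; internal arithmetic is full
precision.

## Synthetic data

`simulate_study` draws, per site: standard-normal site covariates
(forest, agriculture, embeddedness, flow accumulation, pavement),
survey-level covariates (ordinal clarity 1–3, normal depth/time/
temperature/surveyor), and eDNA collection-day covariates (geometric
days-since-rain capped at 14, gamma rain accumulation, normal water
temperature) constant across a site's filters, since filters are drawn
on one visit.  Occupancy is Bernoulli(ψ_i); abundance at occupied sites
is zero-truncated Poisson(λ_i), so z_i = 1[N_i > 0] holds by
construction and the VES and abundance stages see coherent data.  Counts
are Binomial(N_i, p_ind,ij); a survey detects occupancy when its count
is positive, which makes survey-level detection rise with abundance —
deliberate, realistic heterogeneity that an intercept-only occupancy
model does not capture.  eDNA filters are Bernoulli(z_i · p_i) with the
detection logit increasing in density and days-since-rain and decreasing
in temperature and flow accumulation, matching the directions the field
data showed.  Field blanks are structurally negative: no false-positive
mechanism is simulated.  All randomness flows through one seeded
generator; identical seeds give bit-identical outputs.

The default conditions (`default_study_preset`) use λ = 7.5 and an implied
zero mass chosen so that site occupancy is ≈ 0.54 and, with
individual-level detection ≈ 0.28, per-survey occupancy-level detection
lands in the observed 0.84–0.88 band; the per-filter eDNA intercept
(0.10 on the logit scale) was calibrated once against a large-n
simulation to give ≈ 0.57 positivity among occupied sites with the
covariate effects (density +0.6, days-since-rain +0.4, temperature −0.4,
flow −0.3 on the logit scale; ±0.3 effects on VES detection and
abundance) in place, then frozen.  Effect magnitudes are a modeling
choice — the field study reports directions, not sizes.

What passing tests do *not* show about real data: the generator has no
spatial correlation between neighbouring reaches, no eDNA transport or
decay mechanism, no field contamination, no qPCR technical-replicate
layer, and covariates are independent by construction (so the Spearman
screen is exercised but never binds).  Recovery results certify the
estimators under the model's own assumptions plus abundance-driven
detection heterogeneity, nothing more.

## Recovery estimands

`recovery_suite` fits an intercept-only occupancy model and the
generating N-mixture across seeded replicates.  Because survey-level
detection is heterogeneous by construction, the intercept-only ψ and p
are judged against their own large-sample estimands — the MLE on a
single 100,000-site reference draw — which sit within a few thousandths
of the nominal occupancy (0.54) and mean per-survey detection.  λ is
judged against its generating value (7.5), since that fit is correctly
specified.  Replicate sizes in the shipped checks (100 replicates of 500
sites for recovery; 50 replicates of 200 sites for the
density→detection sign-recovery chain; 25 replicates in the acceptance
script) are the package's chosen simulation sizes, balancing Monte-Carlo
error against wall-clock time.

## Known limitations

Site covariates on occupancy must be site-level (no survey-varying
occupancy).  The zero-inflation parameter is shared across sites.  No
overdispersion correction (QAICc) is offered, so model weights inherit
any binomial overdispersion.  Interval coverage for detection under
strong unmodelled heterogeneity runs a few points below nominal — the
recovery suite quantifies this rather than hiding it.  The g-test and
Wald bands are large-sample tools; exact tests are out of scope.
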