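# Methods

`poachmort` estimates age- and sex-specific annual mortality split into
poaching and all other causes, from encounter histories of individually
marked red deer carrying three kinds of marks (ear tags only; ear tags +
optical collar; ear tags + GPS-equipped collar).  The model is a
multievent (hidden-Markov) capture–mark–recapture model combining live
resightings and dead recoveries while accounting for mark change (GPS
signal loss, collar drop-off), mark-dependent detection, incomplete
recovery of carcasses, and uncertainty about the cause of death of
recovered carcasses.

## The hidden-Markov process

Latent states (9): four alive states indexed by current mark status
(working GPS; inactive GPS collar; optical collar; ear tags only), four
"newly dead" states crossing cause of death (poached / other) with mark
group (working GPS / anything else), and one absorbing long-dead state.
Newly-dead states exist for exactly one interval: they emit that
interval's recovery events and then collapse into the absorbing state.

Observed events (11): 0 = not seen; 1–4 = live detections by mark type
(1 = working GPS, which is automatic and certain; 2 = optical collar;
3 = ear tags; 4 = inactive GPS collar); 5–10 = dead recoveries crossing
mark group (working GPS vs other) with assigned cause (poached / other /
unknown).  Recoveries of non-GPS animals are pooled across collar and
ear-tag marks because they are too sparse to stratify.

One annual transition factors as **mark dynamics first, then mortality**:

* mark kernel: a working GPS loses its signal with probability λ_d
  (two deployment-age classes: the year after deployment vs later years)
  and the collar drops off with probability D, reverting the animal to
  ear tags only; optical collars and ear tags are permanent;
* survival: with the post-kernel mark in place, the animal survives with
  probability φ_a = 1 − m_a,poach − m_a,other, where a is the age class of
  the animal's age at the start of the interval.

The order (marks before mortality) is a modelling choice the data cannot
separate at annual resolution; it is isolated in `build_transition` so the
alternative order is a one-line variant.  A dead animal's newly-dead state
carries its post-kernel mark group.

Emissions: a live working-GPS animal yields event 1 with probability one.
Inactive-GPS and optical-collar animals share one "collar-like"
resighting probability (they are detected the same way in spotlight
surveys); ear-tag animals have their own.  A newly-dead animal is
recovered with probability r (by default r_gps = 1 for working-GPS deaths
— a transmitting collar makes the death conspicuous; configurable to share
r).  A recovered carcass is assigned its true cause with probability δ and
otherwise coded unknown-cause; δ is shared across causes and mark groups
(cause-specific δ is not identifiable at these sample sizes).  The
unknown-cause recoveries are thereby redistributed between the causes by
the likelihood itself.

The likelihood of a history is the scaled forward recursion over these
matrices, conditioned on the release.  Initial mark-type proportions are
estimated by default as a multinomial (two free parameters); because the
marking event pins the initial state exactly, this term factors out of
everything else and simply adds the observed-proportion multinomial to the
deviance.  A `conditioned` mode drops the term.

## Parameterization and candidate structures

All free parameters live on link scales (logit; multinomial logit for the
per-age-class (poach, other, survive) triple and for the initial
proportions), so any finite vector maps to valid probabilities and the
optimizer is unconstrained inside a ±15 box (probabilities within ~3e-7 of
0/1; estimates reaching the box are reported as boundary estimates without
Wald intervals).

Mortality-effect structures over an age partition with A classes:
*interactive* (2A parameters), *additive* — the two causes vary in
parallel, i.e. a shared age effect plus one cause offset on the
multinomial-logit scale (A + 1) — and *constant poaching* — one poaching
parameter, free other-cause mortality (1 + A).  The additive scale choice
is the standard multievent-software convention and preserves the
sum-to-≤1 constraint.  Resighting structures: constant, mark,
time, mark + time (additive on logit), mark × time.  Recovery: constant or
time-dependent.  GPS signal loss always has the two deployment-age
classes; drop-off and δ are constant.

Occasions: 11 annual occasions by default.  The first occasion carries
releases only; resighting and recovery parameters attach to occasions
2..11 (time-dependent blocks have 10 levels).  With estimated initial
proportions this bookkeeping reproduces the published identifiable
parameter counts of the study's candidate table (e.g. 21 for the selected
female model, 13 for the selected male model), which is what fixed both
conventions.

## Estimation, model selection, averaging

Maximum likelihood by L-BFGS-B from the null start plus `n_starts` random
starts (multievent likelihoods are multimodal; the best optimum is kept).
Standard errors come from the pseudo-inverse of the observed information
(central finite differences); real-scale SEs by the delta method; 95%
intervals are Wald on the logit scale, hence asymmetric and contained in
(0, 1).  The identifiable parameter count `np` is the numerical rank of
the information matrix: singular values below 1e-6 of the largest
(configurable) count as flat directions — this also discounts boundary
parameters, whose curvature vanishes.

AICc uses an effective sample size equal to the **total number of
non-zero event codes** (releases + resightings + recoveries).  This
definition was adopted because it is the unique one consistent with the
published deviance/np/AICc triples of the study's candidate table
(ess = 357 females, 140 males); it is configurable.

Akaike weights are computed over the three mortality-hypothesis models
only (the structural models fitted during sequential selection are scored
but not weighted).  Model averaging is on the probability scale with the
Burnham–Anderson unconditional standard error
SE_u = Σ w_j sqrt(var_j + (θ_j − θ̄)²); averaged intervals are logit-Wald
around the averaged value.  Mortality estimates are always expanded to one
value per age class, so the constant-poaching model averages cleanly with
the age-dependent ones.  Link-scale averaging is available as an option.

## Goodness of fit

No omnibus test exists for the multievent model, so adequacy is assessed
on the live detections alone (codes 2/3/4; certain GPS detections and
recoveries excluded) against the time-dependent CJS model, with the four
classical contingency-table components (TEST3.SR, TEST3.SM, TEST2.CT,
TEST2.CL) computed per sex and summed.  Sparse tables are pooled by
merging outermost columns inward until every expected count reaches 2;
tables that stay deficient are skipped, with the degrees of freedom
reduced accordingly.  The exact pooling rules of other GOF software are
not published, so the pooled χ² of a given dataset can differ by a few
units from other implementations; calibration is therefore established by
simulation (the type-I error of the pooled test at α = 0.05 is 0.05–0.06
in the acceptance experiments).

## The simulator and what passing tests show

`simulate_histories` draws each animal's yearly mark-kernel, mortality and
observation outcomes from exactly the matrices the likelihood uses, and
records the latent truth.  The default design mirrors the motivating
study: 11 occasions, 56 males (21 ear-tag / 22 optical / 13 GPS) and 85
females (2 / 67 / 16) entering near-uniformly over the first ten
occasions.  Ages at marking are drawn from a geometric-tailed distribution
(weights ∝ 0.8^(age−1), ages 1–13) — captures skew towards younger
animals; this is a design choice, not an estimate.  Parameter presets are
the study's published averaged estimates; the cause-determination
probability is never printed there, so the preset uses the empirical
determined fraction of recoveries (41/50 = 0.82) as a documented stand-in.
Drop-off is simulated through the model's annual probability rather than
the hardware's 3-year timer, so the simulator and likelihood share one
process; the timer is a realism variant the fitted model would absorb into
λ and D.

Because the simulator and the likelihood share their kernels, the
parameter-recovery experiments demonstrate the *estimator's* correctness
(bias, coverage, identifiability at the study's structure), not the
model's adequacy for real deer: real data add features the generator
omits — age misclassification from tooth wear, heterogeneous detection
within mark classes, non-annual death timing, culling-driven temporal
shifts in mortality.  The analysis pipeline would meet those as lack of
fit in the GOF stage and as time effects in selection.

## Numerical choices and problem sizes

Tolerances: optimizer ftol 1e-10; rank threshold 1e-6 (relative); row-sum
conservation asserted to 1e-12; forward-vs-enumeration agreement to
1e-10.  Degenerate inputs: a history with zero probability under a
parameter vector yields −∞ and is reported with the offending id; empty
candidate sets, zero replicates and header-only files return empty
results rather than errors.  The acceptance experiments use 50 replicates
at 2000 animals per sex for parameter recovery (Monte-Carlo SE on a
coverage estimate pooled over the 18 mortality quantities ≈ 0.9%), 200
replicates for GOF calibration, and a single 2000-per-sex surrogate for
the end-to-end reproduction; the bundled scripts default to smaller sizes
that finish in a few minutes and are scaled up by flags.

## Known limitations

* The state/event inventory is reconstructed from the study's verbal
  description (its supplementary design files are not redistributable);
  it is the minimal inventory consistent with every stated fact.
* Wald intervals only; no profile likelihood, no Bayesian fitting, no
  random effects, no overdispersion correction (the motivating study
  applied none).
* δ models failure to *determine* a cause, not misassignment of a wrong
  cause.
* Exact reproduction of other software's AICc can differ in the second
  decimal of the small-sample correction if that software counts its
  effective sample size differently.
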