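# Methods

## The choice model

Each choice task shows two testing profiles plus an opt-out ("none") option.
A profile assigns one level to each of four attributes: test type (3 levels),
specimen type (7), venue (5), result turnaround time (4). The latent class
multinomial logit assumes a finite number of preference classes; respondent
*i* belongs to class *c* with mixing probability π_c, and conditional on the
class the chosen option in each task follows a multinomial logit over the
three options. Option utilities are additive in effects-coded level
part-worths: within each attribute the level utilities sum to zero, the last
level being the implied reference (negative sum of the free coefficients), and
the opt-out option carries a single class-specific constant. With the default
vocabulary this gives 16 free coefficients per class
((3−1)+(7−1)+(5−1)+(4−1)+1) plus K−1 free mixing shares.

The zero-sum parameterization identifies the model: no nonzero effects-coded
coefficient vector produces a constant utility shift across all profiles, so
the opt-out constant absorbs the only location freedom.

## Estimation

EM alternates:

- **E-step** — posterior membership ∝ π_c × Π over the respondent's tasks of
  the class-c probability of the observed choice, accumulated in the log
  domain and normalized per respondent;
- **M-step** — each class's coefficients maximize the conditional-logit
  log-likelihood weighted by its posterior column, by damped Newton iteration
  with analytic gradient and Hessian (the weighted log-likelihood is strictly
  concave, so the Newton system is solvable by Cholesky; steps are halved if
  they ever fail to ascend). Fits are warm-started from the previous EM
  iteration. Mixing shares update to the posterior means.

Because the M-step never decreases the weighted objective, the mixture
log-likelihood is non-decreasing across EM iterations (asserted in tests at
tolerance 1e-8). Each fit runs `n_replications` independent random starts
(posteriors drawn from a flat Dirichlet per respondent) and keeps the highest
log-likelihood; a replication whose smallest share collapses below 1e-6 is
restarted from a fresh seed and logged. Reported classes are ordered by
descending share. Standard errors for the single-class fit come from the
inverse observed information.

Defaults: `max_iter=100` EM iterations, `tol=1e-6` on the log-likelihood
change, 5 replications. On heavily overlapping classes the log-likelihood is
still creeping at 100 iterations (the tolerance is rarely reached); the cap is
kept because longer runs improve the likelihood only marginally and do not
change the qualitative solution (see Limitations).

Model selection sweeps K over a range and reports LL, parameter count,
AIC = −2LL + 2k, BIC = −2LL + k·ln(n_respondents) and the smallest class
share; a failed K is reported with NaNs rather than aborting the sweep.

## Design generation

Tasks are randomized with per-attribute balance: each attribute's levels are
dealt from shuffled balanced decks, so proposal frequencies are near-uniform.
Profiles violating a prohibition (NP swab with either at-home venue) or
duplicating their task sibling are rejected and resampled. Because rejection
operates after balanced proposal, prohibition-affected levels end up mildly
under-represented among shown profiles (the NP swab's expected share is
3/33 ≈ 0.091 instead of 1/7 ≈ 0.143) while all other levels stay within a few
percent of uniform — the behaviour expected of a constrained randomized
design. Generation is deterministic given the seed. D-efficiency optimization
and partial profiles are out of scope.

## The synthetic cohort

`study_fixture_classes()` loads the five-segment fixture (shares 19.2 / 25.8 /
18.5 / 32.9 / 3.6 %). All published class-level utilities and opt-out
constants are stored verbatim; levels without a published value are
reconstructed by splitting each attribute's zero-sum residual equally among
the missing levels and are flagged as reconstructed in the `ClassSpec` — the
reconstruction is an honest filling rule, not data.

Published utilities are display-scale zero-centered values (magnitudes
10–300). Simulated choices apply a configurable multiplier before the logit
(`scale`, default 1/50), chosen so the modal option is picked roughly 80% of
the time; raw display utilities would make choices deterministic and the
recovery problem degenerate. The opt-out constant is multiplied by the same
factor so all options live on one scale. Completion times are log-normal
(median ≈ 180 s, σ = 0.5 on the log scale — a plausible shape for a
five-task exercise); injected speeders draw uniform 10–40 s. Optional
injections add straightliners (all-left or all-right choosers), uniform-random
choosers, and speeders. The generator does not simulate demographics,
attrition, or realistic response-time dynamics beyond what the quality screens
need — so passing tests say nothing about demographic confounding or real
respondent behaviour, only about the estimation and simulation machinery.

`well_separated_classes()` builds the model-selection test bed: class *c*
loves level *c* of every attribute (+120, the rest sharing −120), so any two
classes disagree everywhere and the true class count is unambiguous.

## Post-processing

Individual utilities are posterior-weighted averages of class utilities
(zero-centered by construction). Relative importance per respondent is the
within-attribute utility range over the summed ranges, excluding the opt-out
constant (it is not an attribute level); an all-zero-range respondent gets
uniform importances and a log flag. Class assignment is max-posterior with
ties broken toward the lower class index (logged). Class summaries report
mean, SE = SD/√n (descriptive, within max-posterior classes), and
mean ± 1.96·SE as the 95% CI; singleton classes report a mean with CI marked
unavailable.

## Scenario simulation

Two scenario sets mirror the study's simulations: (1) the two standard offers
(PCR by NP swab, 48-hour results, drive-through or walk-in) plus opt-out;
(2) those plus less invasive (saliva), dual testing (PCR and serology by
finger prick) and at-home (shallow nasal swab, mail return, within 5 days) —
six options. Deterministic first choice picks each respondent's
maximum-utility scenario (exact ties split equally, logged). Randomized First
Choice perturbs, per draw, each attribute-level utility with an independent
Gumbel error (shared across scenarios holding the level) and each scenario
with an independent Gumbel option error, then tabulates first choices over
`n_draws` (default 5000) draws. Exact error magnitudes in the commercial
implementation are not public, so both scales are configuration with defaults
0.1 (attribute) and 1.0 (option); at zero the simulator reduces exactly to
first choice, and with pure option errors of scale 1 the shares converge to
the closed-form logit of the utility gap — both used as oracles in tests.
Monte-Carlo SEs come from the per-draw share variance. Uptake is one minus the
opt-out share. Per-class strata use max-posterior assignments (or the fixture
classes directly via one class-share-weighted pseudo-respondent per class,
which is how the no-refit fixture simulation is run).

## Respondent quality

Straightlining = all of a respondent's choices at the same screen position;
an opt-out choice breaks the pattern; left, right, and their union are
reported separately. Speeders are completion times at or below the 5th or
10th percentile of all times (linear-interpolation percentile, boundary
inclusive — with all times equal, everyone is flagged, by documented
convention). Percentiles are computed over all completers. The
exclusion-sensitivity experiment refits the model without flagged respondents
and compares class shares and each matched class's top-importance attribute,
with classes matched across fits by Hungarian assignment on utility
correlation.

## Numerical choices

- Newton ridge 1e-10·(1 + tr/d) on the negative Hessian; gradient tolerance
  scales with the total task weight (1e-7·Σw).
- Softmax and posterior computations use max-subtraction / log-domain
  accumulation throughout; underflow is treated as a defect, not an error
  path.
- Per-stage seeds derive from one global seed by SHA-256 hashing of the stage
  name (kept below 2^31), so end-to-end runs are reproducible byte for byte.
- Share tables round percentages to 1 decimal, matching the field's display
  convention.

## Limitations

- **Individual class assignment is intrinsically noisy here.** With five
  tasks of two profiles plus opt-out, the five fixture classes — which agree
  on the better profile in most randomly generated tasks — cannot be
  separated at the individual level: even the Bayes-optimal assignment using
  the true generating parameters reaches an adjusted Rand index of only about
  0.12 at the default choice scale (about 0.32 with fully deterministic
  choices). Mixing shares and class-level utilities are likewise weakly
  identified at this overlap (the likelihood is nearly flat across
  reallocations between similar classes), and the recovery experiment in the
  acceptance suite documents exactly this gap. On well-separated classes the
  same estimator recovers partitions (ARI ≈ 0.88) and shares almost exactly,
  so the limit is informational, not algorithmic.
- EM finds local optima; replications mitigate but do not guarantee the
  global maximum.
- Coefficient-level standard errors inside the mixture are not computed;
  uncertainty reporting is limited to descriptive CIs on importances and
  utilities, as in the emulated study's outputs.
- Hierarchical Bayes estimation, covariate-dependent class membership,
  scale-heterogeneity models, willingness-to-pay transforms and demand
  elasticities are out of scope.
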