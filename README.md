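# latentchoice

Latent class multinomial logit (MNL) analysis of discrete choice experiments
(DCEs), built around the stated-preference study design used to measure
SARS-CoV-2 testing preferences: respondents repeatedly choose between two
constructed testing offers (test type, specimen type, venue, result turnaround
time) or opt out, and a finite mixture of conditional logits uncovers distinct
preference segments.

The package is for health-services and preference researchers who want a
transparent, scriptable version of this workflow end to end:

- **design** — randomized, level-balanced choice tasks with prohibited level
  combinations (e.g. a nasopharyngeal swab cannot be collected at home);
- **synthetic cohorts** — a ground-truth latent-class population whose shares
  and part-worth utilities follow the five published preference segments
  (noninvasive home testers, fast-track testers, dual testers, noninvasive
  dual testers, hesitant home testers), so every downstream stage is testable
  without the undeposited respondent-level data;
- **estimation** — EM for the latent class MNL with random restarts, a
  2–10 class sweep, and AIC/BIC/log-likelihood model selection;
- **post-processing** — zero-centered (effects-coded) part-worth utilities,
  posterior-weighted individual utilities, attribute relative importance with
  95% CIs, max-posterior class shares;
- **simulation** — deterministic first choice and Randomized First Choice
  (RFC) share-of-preference over the study's two scenario sets, with uptake
  (one minus the opt-out share) overall and by class;
- **quality** — straightlining and speeder screens plus exclusion-sensitivity
  refits.

## Model

Respondent *i* belongs to latent class *c* with probability π_c. Within class
*c*, the utility of option *j* in task *t* is

    U_icj = Σ_a β_c[a, level_a(j)] + ε_icj            (profiles)
    U_ic,none = γ_c + ε_ic,none                        (opt-out)

with i.i.d. extreme-value ε, so choices follow a conditional logit per class.
Level utilities are effects-coded: within each attribute they sum to zero and
the reference level is the negative sum of the free coefficients. Estimation
alternates posterior class memberships (E-step) with per-class
posterior-weighted conditional logit fits by damped Newton iteration (M-step),
retaining the best of several random starts. Individual utilities are
posterior-weighted averages of class utilities; an attribute's relative
importance for a respondent is its utility range over the summed ranges.

## Worked example

```python
import numpy as np
from latentchoice import (
    CohortSpec, LatentClassMNL, assign_classes, class_share_table,
    simulate_cohort, study_fixture_classes,
)

spec = CohortSpec(classes=study_fixture_classes(), n_respondents=500, seed=11)
observations, truth, design = simulate_cohort(spec)

est = LatentClassMNL(n_classes=3, n_replications=2, max_iter=60, random_state=0)
est.fit(observations)
print(round(est.log_likelihood_, 1), round(est.aic_, 1), round(est.bic_, 1))
print(class_share_table(assign_classes(est.posteriors_)))
```

prints

```
-1276.1 2652.3 2863.0
 class   n  share_pct
     0 254       50.8
     1 231       46.2
     2  15        3.0
```

i.e. a 3-class solution on the 500-respondent synthetic cohort with the best
replication's log-likelihood −1276.1 (AIC 2652.3, BIC 2863.0) and a small
third segment — the hesitant testers, who are only 3.6% of the generating
population. Scenario simulation directly on the fixture utilities:

```python
from latentchoice.replication import rfc_fixture_simulation
print(rfc_fixture_simulation(n_draws=5000, seed=3)["uptake"])
```

```
                 stratum  uptake_sim1_pct  uptake_sim2_pct  delta_pp
                 overall             88.4             98.5      10.1
noninvasive home testers             97.0             99.9       3.0
      fast-track testers             92.7             99.4       6.7
            dual testers             94.4             99.5       5.1
noninvasive dual testers             85.9             99.7      13.8
   hesitant home testers              4.0             67.4      63.4
```

Uptake rises for every segment when the less invasive, dual-testing and
at-home scenarios are added to the two standard offers, with by far the
largest gain among hesitant home testers — the qualitative pattern the study
reports.

A command-line interface mirrors the library
(`latentchoice design|simulate|quality|fit|sweep|postprocess|rfc|report|run-all`).

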