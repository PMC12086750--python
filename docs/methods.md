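# Methods

## Design model

The package designs randomized dose-reduction trials whose primary
decision rests on the *observed* efficacy difference between a reduced
and an approved dose, judged against a pre-specified margin of practical
non-inferiority. Two error-rate-like probabilities are controlled:

- `π_n` — probability of concluding practical non-inferiority (observed
  difference within the margin) when the doses are truly equivalent;
- `κ_n` — probability of concluding practical inferiority (observed
  difference outside the margin) when the reduced dose truly sits at a
  meaningfully worse level, by default the historical control of the
  preceding phase III trial.

The recommended per-arm sample size is `max(n̂_noninf, n̂_inf)` with
`n̂_noninf = min{n : π_n ≥ Q}` and `n̂_inf = min{n : κ_n ≥ Z}`.

### Time-to-event endpoints

Survival is modelled as exponential per arm. The difference of log
hazard-rate estimates is treated as Gaussian with variance `2/(n·p)`,
where `p` is the probability of non-censoring (a single value common to
both arms; accrual and follow-up are not modelled — `p` is an input, not
a derived quantity). The margin is canonically a ratio of medians
`r ∈ (0,1)`; since the hazard ratio equals the inverse ratio of medians
under exponentiality, the margin on the log scale is `ln r`. A margin
given as an absolute width `w` months is converted via
`r = 1 − w/median_approved`. Ties at the margin count as non-inferior
(inclusive `≤` for the non-inferiority event, strict `>` for its
complement); this is measure-zero under the Gaussian but fixed for
consistency with the binary lattice case.

Both argmin searches scan the integers from `n = 1` upward (vectorized
in chunks), capped by `n_cap` (default 100,000); an unmet threshold
raises an error naming the limiting parameter. `π_n` and `κ_n` are
strictly increasing in `n` here, so the first crossing is the argmin;
the scan is kept (rather than an inverse-CDF solve) so the returned
value is the argmin by construction, and it is tested against an
independent linear-scan oracle. The second perspective's reference may
be any median below the approved one, not only the historical control.

Probabilities are kept at full double precision; rounding to whole
percentages happens only in display output.

### Binary endpoints

Per-arm success counts are `k_i ~ Bin(n, p_i)` and the margin is a
difference in proportions. `π_n = Pr((k₂−k₁)/n ≤ m)` is computed
exactly as an O(n) sum of binomial pmf × upper-tail products (the O(n²)
enumeration is retained in the test suite as the independent oracle);
comparisons of the integer difference with `m·n` carry a 1e-9 slack so
exactly-on-margin lattice points are counted inclusively despite
floating-point rounding. Beyond `exact_limit` (default 2,000 per arm) a
seeded Monte-Carlo estimate with `mc_reps` (default 100,000) replicates
is used; each scanned `n` derives its stream from the spec seed, so a
search is bit-reproducible.

`π_n` is **not** monotone in `n` on the lattice — the effective
threshold `⌊m·n⌋` moves with `n` (e.g. with both arms at 0.40 and a
0.05 margin, `π₁ = 0.7600 > π₂ = 0.6928`) — so the searches scan every
integer rather than bisecting.

### Kaplan–Meier layer

IPD is one row per patient (`arm,time,event`; time in months, event 1 =
observed, 0 = right-censored). Curves are product-limit estimates
computed through lifelines; conventions are the standard ones: events
precede censorings at tied timestamps, the median is the smallest event
time with `S(t) ≤ 0.5`, and an unreached median is an explicit value
(`+inf`), not an error. Fixed-time survival reads the right-continuous
step function.

### Bootstrap verification

`bootstrap_verify` simulates the planned trial `reps` times (default
10,000). The equivalence scenario resamples *both* simulated arms, with
replacement and size `n_per_arm`, from the approved arm's data (imposing
exact equivalence); an inferiority scenario resamples the reduced arm
from a designated inferior source. Each replicate computes KM medians
and their approved-minus-reduced difference. Replicates are resampled by
patient (not by event count), with censoring carried by the resampled
records. The replicate loop uses a vectorized product-limit routine
(one replicate per row); it is cross-checked against the lifelines-backed
estimator in the test suite.

Unreached-median policy: an unreached median is `+inf`; the signed
difference then classifies deterministically (reduced-arm unreached →
within the margin; approved-arm unreached with finite reduced median →
outside). Replicates with both medians unreached show no observable
decrement and count as within the margin. All unreached counts are
reported; no replicate is dropped.

### Expected gap between the closed form and the bootstrap

The closed form models the log **rate** difference, whose per-arm
variance is `1/(n·p)`. The bootstrap statistic is a difference of
**medians**, and under exponentiality the sample median is less
efficient than the rate-implied median: `var(ln median̂) ≈ 1/(n ln²2)`,
larger by the factor `1/ln²2 ≈ 2.08`. At the case-study parameters
(n = 300/arm, margin 1.5 months) this asymptotic shifts `P_noninf` from
0.9015 toward ≈ 0.800 and `P_inf` from 0.7966 toward ≈ 0.708. On
synthetic *exponential* data the bootstrap therefore sits about 0.10
*below* the closed form; on real data the direction depends on the shape
of the survival curve near the median — a density steeper than the
exponential's stabilizes the median and pushes both probabilities above
the closed form. The acceptance test encodes this: agreement with a
direct-simulation oracle within 3 combined standard errors is the
quantitative check, and proximity to the closed form is asserted with an
a-priori allowance of 0.105 (the derived asymptotic gap) plus noise.

Sampling from a finite phase-III-scale source adds source-sampling
variability on top of the bootstrap's Monte-Carlo error — substantial
for the inferiority scenario, where the source arms' own median
difference (standard error ≈ 1.5 months at ~380 patients/arm)
propagates into `P_inf`. Tests estimate this component empirically by
regenerating independent sources and combine it with the binomial Monte
Carlo error.

### Margin calibration

`margin_calibration` reports, per candidate margin, the conditional
probability that a trial achieving practical non-inferiority would also
achieve *conventional* non-inferiority — defined as the upper limit of
the `(1 − 2α)` confidence interval for the reduced-vs-approved hazard
ratio falling below a conventional margin on the HR scale. The HR is
estimated per replicate by the exponential-rate MLE
`λ̂ = events / total follow-up time` with log-HR variance `1/d₁ + 1/d₂`;
this self-contained exponential test (rather than a Cox fit) matches the
module's working model and keeps replicates cheap. Replicates with a
zero-event arm cannot bound the HR and count as failing the conventional
test. An empty conditioning set yields an explicit `None`.

### Fixed-time variant

`fixed_time_verify` replaces the median difference with the difference
in KM survival probabilities at a landmark `t*` (e.g. 12 months), for
settings where medians may not be reached; `t*` must lie within the
follow-up of both source arms.

## Synthetic data generator

`gen_exponential_cohort` draws event times `Exp(ln 2 / median)` per arm
and censors them so the expected event fraction equals a target `p`:
exponential censoring uses the closed form `λ_c = λ_e(1−p)/p`;
administrative (uniform) censoring solves the horizon numerically by
root-finding. `p = 1` disables censoring exactly. The generator
reproduces the assumptions of the closed form — independent exponential
arms, non-informative censoring, a common `p` — and deliberately nothing
more: no non-proportional hazards, cure fractions, dependent censoring
or accrual patterns. Passing tests on this generator validate the
calculations *under their own model*; robustness to real-data departures
is exactly what `bootstrap_verify` on user-supplied IPD is for. Default
study conditions mirror the case study: medians 15.1 and 12.7 months,
phase-III-scale sources of 378/377 patients, no censoring, bootstrap at
300/arm with a 1.5-month margin and 10,000 replicates.

## Problem sizes in the test suite

Unit tests run the closed forms at the case-study scale, enumeration
oracles up to n ≈ 100, and reduced-replicate bootstraps (hundreds to a
few thousand replicates). The acceptance test runs the full
10,000-replicate bootstrap plus a 10,000-replicate direct-simulation
oracle and eight 2,000-replicate re-sourced bootstraps for the
source-sampling error estimate; all are vectorized and complete in
seconds. Generator-calibration checks use 10⁵ patients.

## Known limitations

- The exponential model is an approximation; the closed-form `π_n`/`κ_n`
  describe the log-rate statistic, not the KM-median statistic actually
  observed (see the gap analysis above). The bootstrap stage is the
  corrective.
- `p` is a scalar, common to both arms; per-arm censoring and accrual
  modelling are out of scope.
- No conventional non-inferiority sample-size calculator is provided;
  the conventional test appears only inside the margin calibration.
- Reconstruction of IPD from published KM images is out of scope; users
  supply IPD or use the synthetic generator.
- No Greenwood confidence bands: no computation here consumes them.
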