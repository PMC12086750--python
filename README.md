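# pninf

Sample size and operating characteristics for **dose-optimization
(dose-reduction) trials** designed with a **margin of practical
non-inferiority**.

## The problem

A post-approval trial compares a reduced dose of a licensed drug against
the approved dose, hoping to show that efficacy is maintained while
toxicity, cost and quality-of-life improve. A conventional
non-inferiority design — which requires the confidence-interval limit of
the treatment effect to exclude a margin — needs sample sizes that are
rarely feasible in this phase IV setting. The practical-non-inferiority
alternative pre-specifies a margin on the **observed** efficacy
difference instead: if the observed difference in median survival (or in
response proportions) between the reduced and approved doses lies within
the margin, and the pre-specified complementary endpoints (QoL, PK/PD,
receptor occupancy, …) are favourable, the reduced dose is deemed not
materially different. This package computes the sample sizes that make
that decision rule reliable, and verifies them by simulation.

## The model

For a time-to-event endpoint, survival in each arm is taken as
exponential, `T_i ~ Exp(λ_i)`, so the difference of log rate estimates is
asymptotically Gaussian:

    ln λ̂₂ − ln λ̂₁  ~  N( ln HR , 2/(n·p) )

with `n` the per-arm sample size and `p` the probability a patient's
event is observed. Because the hazard ratio equals the inverse ratio of
medians under exponentiality, a margin stated as a ratio of medians
`r ∈ (0,1)` maps to a log-hazard margin `ln r`. Two operating
characteristics drive the design:

- `π_n = Pr( ln r ≤ ln λ̂₂ − ln λ̂₁ )` assuming the doses are truly
  equivalent (the chance of correctly landing **inside** the margin);
- `κ_n = Pr( ln λ̂₂ − ln λ̂₁ < ln r )` assuming the reduced dose truly
  sits at a meaningfully worse median, e.g. the historical control of the
  prior phase III trial (the chance of correctly landing **outside**).

Given thresholds `Q` and `Z`, the recommended per-arm size is
`max( min{n : π_n ≥ Q}, min{n : κ_n ≥ Z} )`. For a binary endpoint the
same two probabilities are computed from exact joint-binomial sums (or
seeded Monte Carlo for large `n`), with the margin a difference in
success proportions.

When patient-level data from the prior phase III trial are available,
`bootstrap_verify` simulates the planned trial by resampling patients
with replacement, computing Kaplan–Meier medians per replicate, and
counting how often the observed difference falls inside/outside the
margin — a direct check of the exponential approximation.

## Worked example

The package's running case study is a dose-reduction question in
metastatic prostate cancer: the approved regimen showed a median overall
survival of 15.1 months against 12.7 months for the historical control,
and a margin of 90% of the approved median is entertained for a reduced
dose.

```python
from pninf import TTEDesignSpec, recommended_n, margin_as_months, \
    prob_practical_noninf, prob_practical_inf

spec = TTEDesignSpec(
    median_approved=15.1,            # months
    median_reference_inferior=12.7,  # months (historical control)
    margin_ratio=0.90,
    q_threshold=0.90,
    z_threshold=0.80,
    p_noncensor=1.0,
)
print(margin_as_months(15.1, 0.90))        # (13.6, 1.5)
print(prob_practical_noninf(300, spec))    # 0.9015436622327331
print(prob_practical_inf(300, spec))       # 0.7966025435060076
print(recommended_n(spec))
# SampleSizeResult(n_recommended=309, n_noninf=296, n_inf=309,
#                  prob_noninf_at_recommended=0.9048361730021779,
#                  prob_inf_at_recommended=0.80007756653885)
```

The margin translates to a threshold median of 13.6 months — a width of
1.5 months. About 300 patients per arm give a ≈90% chance of landing
inside the margin if the doses are equivalent and a ≈80% chance of
landing outside it if the reduced dose is really only as good as the
historical control; the exact argmins are 296 and 309 per arm.

The same from the command line:

```sh
pninf tte-n --median-approved 15.1 --median-reference 12.7 \
    --margin-ratio 0.90 --q 0.90 --z 0.80 --out-json design.json
pninf gen-ipd --arm approved:15.1:378 --arm control:12.7:377 \
    --seed 1 --out-csv ipd.csv
pninf verify-boot ipd.csv --approved-arm approved \
    --reduced-source-arm control --n-per-arm 300 --margin-months 1.5 \
    --reps 10000 --seed 1 --out-json boot.json
```

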