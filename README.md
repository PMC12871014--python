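# asrt — adaptive seamless phase II/III randomization test

Statistical inference for two-stage **adaptive seamless phase II/III designs**
(ASDs) in which treatment arms are selected at an interim analysis on a
short-term **binary response** (e.g. 6-month pathological response) and the
confirmatory comparison is made on **overall survival**.  The package is aimed
at trial statisticians designing or analysing oncology ASDs and at
methodologists running operating-characteristic simulations.

## The problem and the method

In a two-stage ASD, Stage 1 randomizes N_{g,1} subjects to each of G
treatment arms and a control; the arm with the best observed response rate
(or every arm within a margin Δ of the best) proceeds to Stage 2 together
with control.  The final analysis combines stagewise one-sided log-rank
p-values with the weighted inverse-normal rule

    C(p1, p2) = 1 − Φ( w1 Φ⁻¹(1 − p1) + w2 Φ⁻¹(1 − p2) ),   w1² + w2² = 1,

with weights proportional to the square root of the expected number of deaths
contributed by each stage.  The conventional analysis (the combination test
with closed testing and a Bonferroni/Holm/Dunnett Stage-1 adjustment)
controls the family-wise error rate strongly but becomes **conservative**
when the response–survival correlation is weak: the Stage-1 multiplicity
adjustment is driven by max_g Z_{g,1} while the arm actually tested was
chosen on the response, not on survival.

The package's central method replaces the marginal Stage-1 p-value with a
**conditional randomization p-value**.  Holding every subject's (response,
survival) outcomes fixed, the Stage-1 group labels are reallocated at the
fixed group sizes; the pre-specified selection rule is re-applied to each
reallocation, and

    p_{k|Q} = #{ i : Z_k⁽ⁱ⁾ ≥ z*_k and Q(π̂₁⁽ⁱ⁾) = k } / #{ i : Q(π̂₁⁽ⁱ⁾) = k },

i.e. the tail probability of the Stage-1 log-rank statistic **given the
selection event**.  Conditioning restores a uniform null distribution
(the p-clud condition), so C(p_{k|Q}, p_{k,2}) ≤ α is an exact-level test
that adapts automatically to any response–survival dependence.  When the
number of distinct allocations is small the distribution is enumerated
exhaustively; otherwise it is approximated with M* Monte-Carlo
reallocations.  Multi-arm selection conditions on the exact selected set and
applies a Bonferroni/Holm/Dunnett step across the selected arms' combined
p-values.

A Clayton-copula trial simulator (exponential response-time and survival
marginals, Kendall's τ = θ/(θ+2), staggered accrual, administrative
censoring) and a paired Monte-Carlo harness for type I error / power studies
round out the package.

## Worked example

Simulate a three-arm trial (two treatments + control, arm 1 truly better:
3-year survival 0.6 vs 0.5, response rate 0.6 vs 0.5, τ = 0.5), write the
subject-level CSV, and analyse it:

```python
import numpy as np
from asrt import TrialDesignConfig, simulate_trial, write_subjects_csv

cfg = TrialDesignConfig(surv3=(0.5, 0.6, 0.5), resp_rate=(0.5, 0.6, 0.5), tau=0.5)
trial, sel = simulate_trial(cfg, np.random.default_rng(2026))
write_subjects_csv(trial, "trial.csv")
```

```bash
asrt analyze --data trial.csv --config design.yaml --seed 17 --iterations 5000
```

prints (abridged):

```json
{
  "selected_arms": [1],
  "response_rates": [0.48, 0.46],
  "mode": "monte_carlo",
  "n_rerandomizations": 5000,
  "n_selecting": 2483,
  "per_arm": {
    "1": {
      "conditional_p": 0.22271445831655257,
      "stage2_p": 0.02772046420922155,
      "combined_p": 0.02155673170618544,
      "reject": true,
      "friede_reject": true
    }
  },
  "alpha": 0.05
}
```

Reading the output: arm 1 won the interim selection (observed rates
0.48 vs 0.46).  Of the 5000 rerandomizations, 2483 reproduced the selection
event "arm 1 selected"; among those, 22.3% produced a Stage-1 log-rank
statistic at least as large as the observed one, giving the conditional
Stage-1 p-value 0.223.  Combined with the Stage-2 p-value 0.0277 through the
inverse-normal rule (design weights 0.543/0.839), the final p-value is
0.0216 < 0.05, so the selected arm's superiority is confirmed.  The
closed combination-test comparator agrees on this dataset.

Operating characteristics come from the harness, e.g.

```bash
asrt simulate --experiment 1 --scenario null --tau 0.2 --tau 0.5 --tau 0.8 \
    --replicates 1000 --rerandomizations 500 --seed 42 --out exp1.json
asrt summarize exp1.json --power-key rate_any
```

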