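# rrbart

Variable selection for epidemiological data with **missing-at-random
(MAR) covariates and outcomes**, built on Bayesian additive regression
trees (BART) and Rubin's combining rules — plus the comparator methods
and simulation harness needed to benchmark it.

## Who this is for

Analysts of observational health databases who need to identify the
predictors of a binary outcome when a substantial fraction of both
covariates and outcomes is missing, and who want imputation uncertainty
propagated into the selection decision without running a full bootstrap
pipeline for every candidate threshold.

## The method

For a binary outcome the probit BART model is

    Pr(Y = 1 | x) = Φ( Σ_{j=1..m} g(x; T_j, M_j) ),

a sum of m regularized regression trees.  Each posterior draw yields a
**variable inclusion proportion** (VIP) per predictor — its share of all
splitting rules in the ensemble; the VIPs of a draw sum to one.

The selection procedure (pooled across M missForest imputations, P
posterior draws each, VIP_kmp for predictor k):

1. mean_vip_k = Σ_{m,p} VIP_kmp / MP; let k' = argmin_k mean_vip_k.
2. **Gate**: if mean_vip_{k'} > 1/(2K), even the least-used predictor
   claims more than half its equal share — selection is unnecessary and
   all predictors are retained.
3. Distances Δ_kmp = VIP_kmp − mean_vip_{k'} are pooled with Rubin's
   rules: Q̄_k = mean, W_k = within-imputation variance (across-draw
   variance / n), B_k = between-imputation variance,
   T_k = W_k + (1 + 1/M) B_k, df = (M−1)(T_k/(B_k + B_k/M))².
4. Select predictors whose 1−α interval Q̄_k ± t_{df,1−α/2}√T_k excludes
   zero (α = 0.05 by default).

Because no BART library is available as a dependency, the package ships
a lean numba-compiled probit BART (Albert–Chib augmentation,
grow/prune/change Metropolis–Hastings, conjugate leaf values).
Comparators: bootstrap-imputation selection with permutation-null BART
or XGBoost recursive feature elimination (BI-BART / BI-XGB),
missingness-incorporated-in-attributes encodings (MIA-BART / MIA-XGB),
and complete-case analysis.  See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

Generate a synthetic cohort (n = 1000; 10 real predictors X1..X10 with
a nonlinear outcome model; 20 pure-noise predictors), introduce MAR
missingness into X7..X10 and the outcome, and run the pooled selection:

```bash
rrbart simulate --n 1000 --n-noise 20 --seed 11 --out cohort.csv
rrbart select rr-bart --in cohort.csv --m 5 --seed 12 --out selection.json
```

The first command prints the realized missingness and the strength of
the MAR mechanism (the AUC of each variable's missingness model):

```
realized missingness: {'X7': 0.126, 'X8': 0.121, 'X9': 0.113, 'X10': 0.13, 'y': 0.39}
overall: 0.588
MAR strength (AUC): {'X7': 0.899, 'X8': 0.887, 'X9': 0.842, 'X10': 0.888, 'y': 0.855}
```

— about 39% of outcomes and 59% of rows are incomplete, and missingness
is strongly MAR (AUC ≈ 0.84–0.90).  The second command imputes the data
5 times, fits a probit BART to each copy, pools the VIP distances with
Rubin's rules and writes the selected set plus the full pooled-score
table:

```
selected 6 variables -> selection.json
```

with `selection.json` containing (abridged)

```json
{
  "method": "rr-bart",
  "selected": ["X1", "X10", "X4", "X6", "X7", "X8"],
  "gate_triggered": false
}
```

Six of the ten real predictors are recovered with no noise predictor
selected (precision 1.0, recall 0.6 against the generator's truth set);
the moderate binary predictor X2 and the weaker nonlinear terms are the
typical misses at this sample size and missingness level.  Python API
equivalent:

```python
from rrbart import ScenarioConfig, generate_complete, ampute, rr_bart

data = generate_complete(ScenarioConfig(n=1000, n_noise=20, seed=11))
incomplete = ampute(data, seed=12)
result = rr_bart(incomplete, M=5, alpha=0.05, seed=13)
print(result.selected, result.gate_triggered)
print(result.scores)          # per-predictor Q̄, W, B, T, df, CI
```

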