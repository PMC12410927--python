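# branchtime

Semi-supervised Bayesian pseudotime and branch inference from marker-gene
panels in single-cell RNA-seq.

Most trajectory-inference methods are unsupervised: they order cells by
transcriptome-wide similarity and use known marker genes only to validate
the result afterwards.  `branchtime` inverts that workflow for the common
situation where the branching topology of a differentiation system is
already known (e.g. a bipotent progenitor giving rise to two terminal
fates) and a small panel of lineage markers is trusted.  The user declares
K terminal lineages and which panel gene marks which lineage; the package
then infers, jointly and with full posterior uncertainty:

* a pseudotime t_i ∈ [0, 1] per cell,
* lineage proportions π and per-cell branch-assignment probabilities
  p(z_i = k),
* the activation dynamics of every marker gene.

## Model

Expression is normalized per gene (log1p then min–max to [0, 1]).  On the
lineage a gene marks, its mean follows a switch-like logistic curve
μ = 2δ/(1 + e^(−τ(t − t₀))); on other lineages it follows a transient
Gaussian pulse μ = 2η·e^(−ζ(t − t₀)²).  Observations are normal with
mean-dependent variance (1 + φ)μ + ε and zero-inflated by a dropout
indicator with probability logit⁻¹(β₀ + β₁μ).  The per-cell likelihood
marginalizes both the dropout indicators and the lineage assignment (a
K-component mixture), and the joint posterior over (T, π, Θ, φ, β) is
sampled by a NUTS-within-Gibbs scheme written for this model (see
`docs/methods.md`).

Downstream, the entropy of a cell's branch probabilities quantifies its
differentiation potential (high = uncommitted), and branch-specific
dynamic genes are detected by a Bayes factor comparing sigmoidal (M1)
against constant (M0) expression along each branch, with marginal
likelihoods from bridge sampling.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from branchtime import (SamplerConfig, TrajectoryModel, all_branch_f1,
                        default_panel, differentiation_potential, simulate)

# two lineages, four switch-like markers each, 10% dropout
panel = default_panel(n_branches=2, markers_per_branch=4)
ds = simulate(100, panel, dropout_rate=0.10, seed=1)

model = TrajectoryModel(ds.expression, panel)
res = model.fit(SamplerConfig(n_chains=2, n_iter=2000, n_warmup=600, seed=11))

rho = spearmanr(res.pseudotime, ds.true_time).statistic
cls = res.classify(threshold=0.7)
f1 = all_branch_f1(cls.assigned_branch, ds.true_branch)
dp = differentiation_potential(res.branch_prob)

print(f"pseudotime Spearman vs truth: {rho:.3f}")
for k, conf in f1.items():
    print(f"branch {k}: precision={conf.precision:.3f} "
          f"recall={conf.recall:.3f} F1={conf.f1:.3f}")
print(f"mean DP early vs late: "
      f"{dp[ds.true_time < 0.2].mean():.3f} vs {dp[ds.true_time > 0.8].mean():.3f}")
```

Output from the run above:

```
pseudotime Spearman vs truth: 0.818
branch 1: precision=0.958 recall=0.868 F1=0.911
branch 2: precision=0.918 recall=0.957 F1=0.938
mean DP early vs late: 0.098 vs 0.023
```

The inferred ordering tracks the true simulation time (Spearman 0.82 on a
deliberately noisy benchmark — the model's mean-dependent variance keeps
even known-parameter inference well short of a perfect ordering), cells
are assigned to the correct lineage with per-branch F1 above 0.9 at the
0.7 assignment threshold, and the entropy score behaves as a
differentiation potential: early, uncommitted cells carry several times
the entropy of late, committed ones.  `res.summary()` tabulates posterior modes, R-hat
and effective sample sizes per parameter; `res.converged` reports the
joint convergence criterion (all R-hat < 1.05, all ESS > 200).

The same pipeline is available from the shell:

```
branchtime simulate --cells 100 --branches 2 --markers-per-branch 4 \
    --dropout 0.1 --seed 1 --outdir sim
branchtime fit --expression sim/expression.csv --markers sim/markers.yaml \
    --normalized --chains 2 --iter 2000 --warmup 600 --seed 11 --outdir fit
branchtime classify --branch-probabilities fit/branch_probabilities.csv
branchtime evaluate --pseudotime fit/pseudotime.csv --truth sim/truth.csv
branchtime test-genes --expression sim/expression.csv \
    --pseudotime fit/pseudotime.csv --classification classified/classification.csv
```

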