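# blockmc

Clustering and model evaluation for discrete sequential data with **block
Markov chains** (BMCs).

Many long observation sequences — codons along a gene, grid-binned animal
GPS tracks, word streams, daily top-performing stocks — take values in a
large finite state space `[n]` whose states are individually noisy but
collectively organized: groups of states transition *to* and *from* the rest
of the space in the same way.  A block Markov chain formalizes this.  A
cluster assignment `σ: [n] → [K]` partitions the states into clusters
`V_1, …, V_K`, and the transition kernel is

```
P_ij = p_{σ(i), σ(j)} / #V_{σ(j)}
```

for a row-stochastic `K × K` cluster matrix `p`: the next cluster depends
only on the current cluster, and the state inside the destination cluster is
uniform.  If `p` is ergodic with stationary law `π`, the chain's state
equilibrium is `Π_j = π_{σ(j)} / #V_{σ(j)}`.

`blockmc` provides:

* **Fitting** — the two-step estimator: a spectral initialization on the
  (optionally degree-trimmed) transition-count matrix `N̂`, followed by
  hill-climbing of the BMC log-likelihood
  `Σ_t ln( p_{σ(X_t),σ(X_{t+1})} / #V_{σ(X_{t+1})} )`
  over single-state cluster moves with `p` profiled out at its MLE.
* **Evaluation** — holdout Kullback–Leibler divergence-rate comparison of
  fitted models (train on the first half, score the second, circular
  block-bootstrap CI); Markov-order selection for the clustered sequence by
  the Consistent AIC, `CAIC(r) = −2 lnL + 2 K^r(K−1) (1 + ln(ℓ−r))`;
  misclassification and spectral-norm estimation-error metrics.
* **Spectral-noise diagnostics** — bulk singular-value spectra of
  `N̂/√n` and `√n L̂` (`L̂` the normalized Laplacian,
  `L̂_ij = N̂_ij / √(rowsum_i · colsum_j)`), a Monte-Carlo predictor of
  the bulk under a fitted model, and the quarter-circle reference density
  `f(x) ∝ √(c² − x²)` expected for the Laplacian bulk of a 0th-order chain.
* **Simulation** — seeded generators for BMCs of any Markov order `r`
  (including the i.i.d. `r = 0` case), perturbed kernels
  `(1−ε) P_BMC + ε Δ`, and planted-cluster models for experiments.
* **Data front-ends** — FASTA → 64-state codon paths, 2-D trajectories →
  grid-cell paths, self-jump removal, per-document count-matrix summing.

## Worked example

Fit a 3-cluster BMC to a sequence simulated from a known model over
`n = 60` states (20 per cluster) with cluster matrix
`p = [[0.9, 0.1, 0], [0, 0.1, 0.9], [0.3, 0.7, 0]]`:

```python
import numpy as np
from blockmc import BlockMarkovChain, models, simulate

p = np.array([[0.9, 0.1, 0.0],
              [0.0, 0.1, 0.9],
              [0.3, 0.7, 0.0]])
truth = models.make_bmc(models.ClusterAssignment.balanced(60, 3), p)
path = simulate.sample_model_path(
    truth, simulate.SimulationConfig(length=50_000, seed=1))

res = BlockMarkovChain(path, K=3).fit(seed=0)
print(res.summary())
print(res.select_order(r_max=3))
```

```
Block Markov chain fit
==============================================
states n            : 60
clusters K          : 3
trimmed states Gamma: 0
improvement sweeps  : 1
log-likelihood      : -168904.8356
seed                : 0

cluster sizes (1-based labels):
  cluster 1: 20 states
  cluster 2: 20 states
  cluster 3: 20 states

cluster transition matrix p_hat:
  0.1002  0.0000  0.8998
  0.1009  0.8991  0.0000
  0.7016  0.2984  0.0000

 r         CAIC  DF  increase_vs_best_pct
 0 96772.547600   2            152.115102
 1 38384.272474   6              0.000000
 2 38667.006166  18              0.736587
 3 39506.176680  54              2.922823
```

The fitted `p̂` matches the generating matrix up to a relabelling of the
clusters (clusters are reported in decreasing-size order, ties by label),
and each entry is within ~0.002 of the truth.  The CAIC table says the
clustered sequence is best described as a 1st-order chain — exactly the
generating order: the order-0 fit pays an enormous likelihood cost, while
orders 2 and 3 buy no fit for `K^r(K−1)` extra parameters.

Real data enters the same way:

```python
model = BlockMarkovChain.from_fasta("gene.fasta", K=5)   # 64 codon states
res = model.fit(seed=0)
```

or from the shell:

```sh
blockmc codons --input gene.fasta --output codons.txt
blockmc cluster --input codons.txt --k 5 --seed 0 --output fit
# order-select takes the clustered sequence, i.e. the path mapped through
# the fitted assignment (fit.assignment.tsv)
blockmc order-select --input clustered.txt --k 5
```

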