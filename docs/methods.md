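# Methods

## Model

`treemhn` models the evolution of a tumor as a continuous-time branching
process over *subclones*. A subclone is identified with the ordered sequence
of mutations π = (0, σ₁, …, σ_d) on its root-to-node path in the tumor's
mutation tree; the root 0 is the wild type. From an existing subclone π,
each mutation i ∉ π fixates after an exponential waiting time with hazard

    λ_(π,i) = exp(θ_ii + Σ_{j∈π} θ_ij) = Θ_ii · Π_{j∈π} Θ_ij ,

parameterized by the Mutual Hazard Network Θ = (e^{θ_ij}): diagonal entries
are baseline log-rates, off-diagonal θ_ij is the promoting (positive) or
inhibiting (negative) log-effect of an ancestor mutation j on mutation i.
An independent sampling event S with time T_s ~ Exp(λ_s) censors the
process: the observed tree contains exactly the subclones born before T_s.
λ_s is fixed to 1 by default for identifiability; all waiting times are in
units of 1/λ_s and have no calendar-time interpretation.

Parallel mutations in different branches are allowed (the model does not
need the infinite sites assumption); back mutations, subclone sizes and
fitness are outside the model.

### Exact likelihood

The marginal probability of a tree T is the probability that every observed
event precedes T_s and every unobserved next event of the augmented tree
A(T) follows it. Marginalizing T_s yields an absorbing Markov chain on the
lattice of rooted subtrees of T: state S jumps to S ∪ {v} with rate λ_v for
each observed event v attachable to S, while attachable unobserved events
contribute only to the exit rate. With states ordered subsets-before-
supersets, λ_s·I − Q is triangular and

    p(T | Θ) = λ_s · [(λ_s I − Q)^{-1}]_{{root}, T}

is a single forward substitution of cost linear in (states × events). The
gradient with respect to every event rate comes from one adjoint (reverse)
sweep of the same recursion, and the chain rule maps rate-gradients to θ:
diagonal θ_kk collects λ_v ∂log p/∂λ_v over events with label k, and
off-diagonal θ_kj additionally requires j on the event's parent path. The
matrix dimension is the number of rooted subtrees of T — the model's
complexity is governed by the largest tree, not by n.

## Estimation

Θ̂ maximizes Σ_l log p(T_l|Θ) − γ Σ_{i≠j} |θ_ij| with γ > 0.

* **Direct MLE** (all trees with ≤ `subtree_threshold` = 500 subtrees):
  L-BFGS-B on the exact likelihood with analytic gradients.
* **Hybrid MC-EM** (otherwise): the E-step computes E[T_(π,i) − T_π | T, Θ]
  for every event of A(T) — exactly as 1/λ − ∂log p/∂λ for small trees, and
  for large trees by self-normalized importance sampling with M = 300 draws:
  the sampling time is drawn first, then truncated-exponential gaps in
  topological order (observed events truncated below the residual time,
  unobserved ones above it), so every draw is tree-compatible; the weights
  are the products of the corresponding truncation masses. The M-step
  maximizes the resulting concave expected complete-data objective.

Numerical choices:

* L1 is smoothed as |x| ≈ √(x² + δ), δ = 1e-8, keeping a single smooth
  optimizer; off-diagonals with |θ̂| < `zero_tol` = 1e-2 are reported as
  exact zeros. Support recovery is delegated to stability selection, not to
  the raw penalized fit.
* θ entries are box-bounded to [−10, 10] and log-rates clipped at 30 before
  exponentiation, preventing rate overflow.
* Initialization: zero off-diagonals; θ_ii = log(m_i/N) − log(mean tree
  size + 1), clipped to [−8, 2], where m_i counts trees containing mutation
  i — a crude independent-rates guess. The exact-likelihood objective is not
  concave in general, so a frequency-based start is used and kept fixed.
* EM stopping: relative change of the penalized observed-data objective
  below 1e-6 when all E-steps are exact (monotonicity then holds and is
  asserted in tests). With Monte-Carlo E-steps the parameter updates carry a
  noise floor of order M^{-1/2}, so the EM instead stops on a plateau: once
  the step size no longer shrinks relative to its recent history (or after
  `max_em_iters` = 200 iterations), further iterations only resample the
  same stationary point.
* Identical trees are grouped and weighted by multiplicity before fitting;
  per-tree weights are honored, so posterior-weighted cohorts (several
  candidate trees per patient) are supported. By default each tree counts
  once.

### Stability selection

With n² parameters and a few hundred trees, single fits overfit. Over B
subsamples of ⌊fraction·N⌋ trees (without replacement) and a penalty grid,
an off-diagonal counts as selected when its estimate survives thresholding;
its reported frequency is the maximum over the grid of the per-γ selection
fraction. Entries at or above `freq_threshold` form the stable support, and
the final network is refit on all trees with the complement pinned to zero.
Defaults follow common stability-selection practice — B = 100,
fraction = 0.5, threshold = 0.95 — and are fully configurable; per-γ
frequencies are also reported so users can apply their own cutoffs.
Subsample fits run on seeds derived from the master seed and are independent,
so parallel and sequential execution give identical results.

## Trajectories

A sampling-terminated trajectory (0, σ₁, …, σ_d, S) has probability equal to
the product of competing-exponential factors λ/(λ_s + Σ pending λ) along the
path, with the sampling factor last; these sum to one over all trajectories.
Expected waiting times are the sums of the segment means 1/(λ_s + Σ pending).
Top-K enumeration is a best-first search over prefixes: the accumulated
product of transition factors bounds any completion from above (every factor
≤ 1), which makes the bound admissible; the search is validated against
exhaustive enumeration for n ≤ 4. Fixed-length distributions over ordered
d-tuples drop the sampling clock and renormalize; d = 4 is the default
comparison length and the tuple count n!/(n−d)! is capped at 10⁶. KL
divergences between fixed-length distributions mix both sides with the
uniform distribution at weight 1e-12, so estimated distributions with empty
support stay finite; a strict mode raises instead. Natural logarithms
throughout.

## Prediction

Given a tree, the candidate next events are the unobserved events of A(T);
their probabilities are rates normalized over the candidates. Ranks use the
midrank convention on a 0–100 scale: rank = 100·(c_below + 0.5·c_tie)/K,
with c_tie the full tie group, so a complete tie scores 50 and the largest
of K distinct values scores 100·(K−0.5)/K. Retrospective evaluation
enumerates every rooted subtree (the root-only subtree included) with every
downstream event whose parent lies in the subtree; the full tree contributes
no pairs. Forward evaluation scores the new events of a later tree whose
parent path exists in the earlier tree; other new events are reported as
unscoreable rather than dropped. Two baselines are built in: the
diagonal-only refit (off-diagonals pinned to zero — independence between
mutations with the tree structure respected) and the cohort-frequency model
(uniform placement node × relative mutation frequency, renormalized).

## Synthetic data

The generator emulates cohorts of the kind the model targets (single-cell /
multi-region panels of a few hundred tumors): baseline log-rates uniform on
[−6, −1], a `sparsity` = 0.5 fraction of off-diagonals at zero, the rest
with Gamma(4, rate 2.5) magnitudes (mean 1.6) and negative signs with
probability 0.5. The Gamma parameter is interpreted as a rate by default
(mean α/β); a `scale` switch is exposed since either convention appears in
practice. Trees are drawn by simulating the generative process directly
(with a 10⁵-node runaway guard). Tree noise perturbs each non-root node
independently with probability ε by relabeling within validity constraints,
pruning-and-reattaching its subtree under a uniformly chosen valid host, or
a fair mix of both (the default); nodes with no valid move are skipped, so
outputs are always valid trees.

What the simulations do not emulate: phylogenetic reconstruction error
beyond the explicit ε-perturbation, within-patient tree posterior
uncertainty, subclone sizes, treatment effects, and mutation-rate
heterogeneity across patients. Passing tests therefore demonstrate the
correctness and internal consistency of the method under its own generative
assumptions, not robustness to real-data violations of them.

## Problem sizes used in the shipped studies

The test suite and the acceptance script run scaled-down study presets
chosen to exercise every code path on one CPU in minutes: network recovery
at n = 8 mutations, N = 200 trees, γ = 0.5, five replicates, with stability
selection over 20 half-subsamples at threshold 0.8; trajectory-distribution
consistency at n = 5, d = 4, N ∈ {100, 500}; prediction on n = 6 cohorts of
150 training and 30 held-out trees. The random-sign reference for recovery
metrics is the guesser that declares every off-diagonal non-zero with a
uniform random sign (expected precision = true density/2, expected
recall = 1/2). Full-scale sweeps (larger n, N, 100 repetitions) run through
the same `benchmark_run` interface.

## Known limitations

* Exact likelihood and E-step require the subtree lattice; trees beyond the
  50,000-subtree cap are only usable through the Monte-Carlo path.
* The penalized objective is non-convex; different starts can reach
  different local maxima. The shipped initialization is deterministic, and
  EM/MLE agreement is asserted in tests only on small cohorts.
* Waiting times are relative to the unknown sampling-rate scale.
* Percentile ranks depend on the stated midrank convention; tables produced
  under other conventions are comparable only after conversion.
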