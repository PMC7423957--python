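# Methods

This note records the model, the numerical choices and the limitations of
the implementation, in the spirit of a methods appendix.

## Model overview

The method embeds *n* samples described by *m* feature matrices ("views")
into a shared low-dimensional space and clusters the embedding.

1. **Per-view neighbour distributions.** Within each view, squared
   Euclidean distances are turned into row-conditional Gaussian neighbour
   probabilities with per-sample bandwidths calibrated so each row's
   Shannon entropy (nats) equals log *k*. This is the perplexity-style
   calibration of stochastic neighbour embedding; *k* is the effective
   neighbour count. Each row sums to one over the samples present in the
   view and the diagonal is zero. We adopt the row-conditional convention
   throughout: it is the only reading under which the downstream
   renormalization and the gradient derivation (which assumes the joint
   distribution sums to one) are coherent.

2. **Conflation.** The per-view distributions are combined per pair (i, j)
   with a binary odds form: the product over views of "j is i's neighbour"
   probabilities against the product of the complementary masses,
   `p_ij = Π p^v_ij / (Π p^v_ij + Π (1 − p^v_ij))`, evaluated in log-space
   (`log1p`/`expit`) so products over views of hundreds of tiny
   probabilities cannot underflow. Because this raw form is not
   row-stochastic, rows are renormalized before the joint symmetrization
   `p_ij ← (p_ij + p_ji) / 2n`; a literal mode without renormalization is
   kept behind a flag for fidelity experiments. Conflation weights views by
   precision automatically — the property the AvgProb baseline (arithmetic
   mean of the rows) deliberately lacks.

3. **Incomplete views.** When samples are missing from some views the
   combination is case-wise: a sample observed in a single view keeps that
   view's row; for a pair with the *column* sample observed in a single
   view and the row sample in several, the single view's probability is
   divided by the number of views *m*; otherwise conflation runs over the
   views containing both samples. With complete data the rule reduces
   exactly (bitwise, in this implementation) to the complete-data formula.
   Pairs sharing no view get probability zero.

4. **Embedding.** Low-dimensional coordinates Y induce a Student-t
   (1 d.o.f.) joint distribution Q; Y minimizes KL(P‖Q) with the
   closed-form gradient, full-batch, 2000 iterations by default, base
   learning rate η = 200, momentum 0.5 switching to 0.9 (default switch at
   iteration 250), and Jacobs-style per-coordinate gains (+0.2 on sign
   disagreement between gradient and velocity, ×0.8 otherwise, floor 0.01).
   Y is recentred each iteration (the cost is translation invariant).

5. **Initialisation.** Y starts from the bottleneck of a stacked denoising
   autoencoder (layers d–500–d_emb–500–d, ReLU, 5% dropout corruption on
   layer inputs during training, mean-squared reconstruction error) trained
   on the zero-filled horizontal concatenation of the z-scored views:
   greedy layer-wise pretraining followed by end-to-end fine-tuning, Adam,
   learning rate 1e-3, batch = min(n, 64), 200 + 400 epochs by default.
   The final decoder activation is linear because inputs are z-scored
   reals. Encoding always uses clean (uncorrupted) forward passes. The
   network is implemented directly on numpy — cohort-sized problems do not
   need a deep-learning framework — and is fully seeded. A PCA initializer
   is available (`init="pca"`).

6. **Clustering.** Archived multi-objective simulated annealing over
   variable-length center lists (2 ≤ K ≤ ⌊√n⌋), minimizing the Xie–Beni
   index (crisp memberships, squared Euclidean distances) and maximizing
   the PBM index (Euclidean distances, the printed un-squared form)
   simultaneously. Mutations: Laplace perturbation of one center
   (scale 1.0), insertion of a random data point as a center, deletion of a
   random center; out-of-range moves are redrawn. Schedule: T from 100 to
   0.001, cooling 0.9 (110 temperature levels), 100 iterations per level;
   archive soft/hard limits 50/40 with single-linkage pruning in normalized
   objective space. A dominated candidate is accepted with probability
   1/(1 + exp(Δdom_avg/T)), Δdom_avg being the average range-normalized
   amount of domination, so uphill moves die out as T cools. Empty clusters
   are repaired by moving the empty center onto the point farthest from its
   assigned center. From the final Pareto archive the default report is the
   best-PBM solution; an explicitly labelled supervised mode (best NMI
   against given labels) exists because published comparisons are often
   reported that way — it uses ground truth and is flagged in the output.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 30 | entropy target log k of the Gaussian rows; too small fragments clusters, too large merges them |
| `d_emb` | 80 | embedding dimension; the heavy-tailed Student-t kernel degrades if it is very large |
| `n_iter` | 2000 | gradient-descent iterations |
| `eta` | 200 | base learning rate, scaled per-coordinate by adaptive gains |
| momentum | 0.5 → 0.9 at iter 250 | standard two-phase schedule |
| SAE layers | d–500–d_emb–500–d | bottleneck = embedding size; dropout 0.05 |
| anneal | T: 100 → 0.001, ×0.9, 100 iters/level | 110 levels; SL/HL 50/40 |

## Numerical choices

- **Probability floor.** Entries are floored at 1e-12 before any logarithm
  (inside conflation products and the KL cost), as every SNE-family
  implementation must.
- **Bandwidth search.** Doubling bracket then up to 50 bisection steps on
  σ, tolerance 1e-5 on the entropy; rows whose neighbours are all
  equidistant are uniform for any σ and short-circuit. An unreachable
  entropy target (fewer distinct neighbours than the target requires)
  returns the boundary σ with a warning.
- **Variance estimator.** Feature variances and z-scores use the
  population (1/n) convention; the ranking is invariant to the choice, and
  fixing one keeps tests deterministic. Statistics never include the
  zero-filled rows of absent samples.
- **Stationary-point guard.** With η = 200 the momentum/gain dynamics are
  locally unstable at a minimum: a numerically zero gradient (~1e-17) would
  be amplified into a bounded limit cycle. The optimizer therefore freezes
  the update whenever the gradient sup-norm falls below 1e-12, which makes
  exact stationary points genuinely stationary.
- **Initial spread.** The pipeline rescales the initial embedding to a
  small spread (std 0.01) before gradient descent — the standard SNE
  practice of growing the map rather than untangling a large one. Without
  it the first iterations can destroy the initializer's structure. The
  rescale is off by default in the raw `optimize()` function so the pure
  gradient-descent contract holds.
- **Tie-breaks.** Variance ranking and marker selection break ties by gene
  order (up-markers prefer earlier genes, down-markers later ones);
  nearest-center assignment breaks ties toward the lower center index.
- **Degenerate inputs.** Coincident points fall back to uniform rows with a
  warning; coincident cluster centers give XB = +inf (and are never
  selected); all-identical data yields a degenerate two-cluster archive
  with a warning.

## Synthetic data

The generator draws K cluster centers per view in random directions,
rescaled so the minimum pairwise center distance equals the requested
separation, and adds isotropic Gaussian noise; cluster assignments are
shared across views. Views may differ in dimension and noise, and a
per-view fraction of samples can be flagged missing (never from all views
at once). Defaults follow a small multi-omics cohort: three views of a few
hundred selected features, four clusters, separation/noise = 6 — a regime
where each single view is cleanly clusterable, so what the multi-view tests
certify is the *combination* machinery, not rescue of hopeless views. The
generator does **not** emulate realistic omics noise (batch effects,
count over-dispersion, methylation beta distributions, dropout zeros), so
passing tests demonstrate correctness of the algorithms, not performance on
real cohorts.

Test and acceptance runs use deliberately scaled-down problem sizes —
n = 200 samples, views of 40/30/40 features, d_emb = 10, SAE with 128
hidden units trained 40 + 80 epochs, 500 gradient-descent iterations
(1000 for the convergence trace), 30 annealing iterations per temperature
level — chosen so the entire suite reruns in minutes while keeping every
stage's behaviour representative.

## Known limitations

- **Quadratic cost.** Distances, conflation and the embedding gradient are
  all O(n²); no Barnes–Hut-style approximation is provided. The method
  targets cohort-sized data (hundreds to a few thousand samples).
- **Incomplete-view scale mixing.** The case-wise combination rule places
  raw single-view probabilities (scale ~1/k) next to conflated odds-form
  entries (scale ~(1/k)^m) in the same row; after renormalization,
  single-view samples act as high-mass hubs. The embedding still clusters,
  but between-cluster geometry is compressed, and on some draws with 20%
  per-view missingness the XB/PBM-optimal archive solution merges true
  clusters (K too small) even though the embedding itself separates them
  (k-means at the true K scores NMI > 0.9). This is a property of the
  combination rule as defined, not of the optimizer; supervised selection
  from the archive does not exhibit it.
- **Validity-index bias.** PBM's max-separation term favours small K when
  clusters form super-groups; unsupervised best-PBM selection inherits that
  bias. The Pareto archive retains the alternatives, so a different
  selection rule can be applied without re-running the annealer.
- **No convergence guarantee.** Constant-step momentum descent settles
  into a tiny limit cycle rather than a point; cost traces are monotone in
  trend (100-iteration moving average) but not iteration-by-iteration.
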