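# Methods

## Model

`ipadpy` estimates drug–pathway associations by a joint penalized matrix
decomposition. Two observation matrices share one latent factor matrix:

    Y1 = X B1 + E1        (N samples × G1 genes)
    Y2 = X B2 + E2        (N samples × G2 drugs)

- `X` (N × K): latent pathway activity per sample. Each column is
  constrained to the unit Euclidean ball, which fixes the scale
  indeterminacy of the factorization.
- `B1` (K × G1): gene loadings, with `B1[i, j] = 0` wherever the binary
  prior `H1[i, j] = 0`. The gene–pathway membership prior is treated as
  complete and trusted; it is what gives the latent factors their
  pathway identity (without it the factorization would be rotation
  invariant).
- `B2` (K × G2): the drug–pathway associations of interest, penalized by
  `λ1 ||B2||_1 + λ2 ||B2||_{2,1}`. The element-wise term yields scattered
  sparsity; the row-wise term (sum of row norms) switches entire pathways
  off across all drugs; their sum yields row structure with intra-row
  sparsity. `λ2 = 0` is the lasso-only decomposition (iPaD); `λ1 = 0` the
  row-sparse variant (L2,1-iPaD); both are exact special cases of the one
  solver, verified in the tests against independently coded baselines.
- An optional binary drug–pathway prior `H2` marks associations already
  known: those coefficients are ridge-penalized (`λ2 b²`) instead of
  sparsity-penalized, and the L1/L2,1 terms run over the `H2 = 0` cells
  only. With `H2 = 0` everywhere (the common setting) the objective is
  exactly the mixed-penalty form above. `fit` traces this H2-aware
  objective; `objective()` computes the plain form.

Missing cells in `Y2` (a fact of life for drug panels) are excluded from
the loss. Loaders z-score each column over its observed entries by
default (recorded on the dataset, disable with `--no-standardize`),
which puts genes and drugs on the scale-free footing the unit-ball
constraint and a 0/1 prior assume.

## Solver

The problem is bi-convex; each block subproblem is convex and is solved
(essentially) exactly, so the objective decreases monotonically — this is
asserted after every outer iteration and tested on random instances.

- **X update** — with `Y = [Y1, Y2*]`, `B = [B1, B2]` (`Y2*` = `Y2` with
  unobserved cells soft-imputed by the current prediction `X B2`, which
  makes the complete-data quadratic a majorizer of the masked loss):
  projected gradient with Nesterov acceleration. The automatic step is
  `1 / (2 ||B Bᵀ||_2)` (inverse gradient-Lipschitz constant, recomputed
  each outer iteration), so the plain step is guaranteed to descend;
  momentum is restarted whenever acceleration plus projection would
  increase the inner objective. Per-column rescaling onto the unit ball
  is the exact projection for the per-column constraint.
- **B1 update** — exact restricted least squares per gene, on the
  pathways its `H1` column allows. Genes sharing a support pattern are
  solved together from the K×K normal equations, batched across patterns
  of equal support size; rank deficiency falls back to minimum-norm
  least squares with a logged warning.
- **B2 update** — iteratively reweighted ridge (IRLS) in matrix form.
  Each sweep solves, for every drug column simultaneously, a ridge
  system `(XᵀX + diag(w)) b = Xᵀy` with weights
  `w = λ1/(2|b| + ε) + λ2/(2‖row‖ + ε)` built from the current `B2`
  (known `H2` cells get the constant ridge weight `λ2`). By the AM-GM
  inequality the weighted quadratic majorizes the exact penalty for any
  ε > 0, so every sweep descends; sweeps are iterated to a fixed point,
  which is the global minimizer of the convex B2 subproblem (each column
  then satisfies its own per-column optimality condition, checked in the
  tests against a per-coordinate convex solver to 1e-5). Only the
  observed rows of each drug column enter its system, which is exactly
  the masked loss.

Initialization follows the natural scheme: `B1 = H1`, `B2 = 0`, `X`
standard normal columns projected to the ball, seeded by `cfg.seed` for
bit-reproducibility. Outer iterations stop when the relative objective
change falls below `tol_rel_obj` (default 1e-6) or at `max_outer_iter`
(default 500).

### Numerical choices

- `eps_reweight` (default 1e-10) guards the IRLS denominators; exact
  zeros are handled by the guard and cleaned up by snapping.
- `zero_threshold` (default 1e-6) snaps `|B2|` entries below
  `1e-6 × max(max|B2|, s)` to exact zero, where `s` is the data-derived
  single-coefficient scale `max|XᵀY2| / max(diag XᵀX)`. The floor `s`
  matters in one regime: when the true solution is the zero matrix, IRLS
  approaches it geometrically and a threshold relative to `max|B2|`
  alone would keep ε-sized entries formally nonzero forever.
- The inner IRLS stopping test is purely relative
  (`Δ ≤ tol · ‖B2‖`): a coefficient escaping the zero start grows
  geometrically from ~1e-10, and any absolute floor in the test would cut
  the escape off and freeze the support (this failure mode is easy to
  reproduce and is covered by the recovery tests).
- Objective monotonicity is enforced with slack `1e-8 · max(1, |f|)`,
  absorbing snapping and round-off; three consecutive violations abort
  with a diagnostic naming `step_mu`.

### Known limitations

- Bi-convex alternation converges to a stationary point, not necessarily
  the global optimum. On some noiseless instances the alternation stalls
  at a nonzero residual regardless of the random X seed (the first X
  pass is essentially determined by `B1 = H1`, so restarts do not help);
  on others it reaches the exact factorization to machine precision.
- `lambda_max` (the smallest penalty with an all-zero B2, computed from
  the stationarity condition at the penalty→∞ fit) brackets the support
  for fits warm-started from that same null model — the regularization
  path setting it exists for. A cold random start just above the
  threshold can occasionally retain a coefficient that escaped during
  early, not-yet-converged X iterates.
- Near the entry threshold of a pathway row, the group penalty makes
  both IRLS and any generic solver converge sublinearly; path grids that
  sample exactly at such a boundary can take many iterations at that
  grid point.

## Inference

- **Permutation test** — the null hypothesis is "no coupling between
  drug response and the expression-driven pathway activities". Each of T
  permutations independently reshuffles the sample rows of `Y2` (with its
  missingness mask) and re-runs the complete fit; `P[i,j]` is the
  fraction of null `|B2|` values at least as large as the observed one,
  so P-values live on the grid {0, 1/T, …, 1}. A fast mode (off by
  default) freezes `X` at the reference fit and re-estimates only `B2`.
  Under a global null with zero penalties the P-values are uniform by
  exchangeability, which the calibration test checks (KS < 0.1,
  false-positive rate at 0.05 within [0.02, 0.08] at T = 200).
- **Regularization path** — a log-spaced grid of 50 points over three
  decades below `lambda_max`, scaling (λ1, λ2) together at a fixed ratio
  (default 1), warm-starting each fit from the previous solution. The
  grid index at which each coefficient first becomes nonzero is its
  entry order; earlier entry indicates a stronger association.
- **Cross-validation** — the observed cells of `Y2` are partitioned
  entry-wise into 5 near-equal folds (an entry-level split: a row-level
  one would leave held-out samples with no training signal). Each fold
  in turn is made missing, the model re-fitted, and the held-out cells
  scored against `X B2`. Following a coordinate search, λ1 is scanned
  with λ2 at its grid midpoint, then λ2 at the chosen λ1; a full 2-D
  grid is available behind a flag.
- **Ranking** — identified pairs are those with `P ≤ α` (default 0.05)
  and a nonzero coefficient, sorted by P then |coefficient|;
  Benjamini–Hochberg q-values are attached for reference but the
  identification rate (identified / K·G2) uses the raw cutoff.

## Synthetic data

`simulate` draws from exactly the generative model above: unit-norm
latent columns, Bernoulli `H1` (with an at-least-one-gene repair per
pathway row to keep every pathway identifiable), `B1 = H1 ⊙ N(0,
effect_size²)`, a `B2` with a chosen fraction of active pathway rows and
Rademacher ± effect_size entries within them, i.i.d. Gaussian noise and
a Bernoulli missingness mask on `Y2`. Defaults mirror curated-panel
priors (gene–pathway density 3.95%, drug–pathway 0.51%).

`benchmark_spec()` defines the desk-scale conditions used by the
recovery and calibration studies: N = 100 samples, K = 8 pathways,
G1 = 200 genes, G2 = 15 drugs, and a gene–pathway density of 0.3. The
density choice is structural, not cosmetic: what anchors the latent
factors is the prior's geometry — a few pathway memberships per gene and
tens of member genes per pathway, as a ~58-pathway KEGG prior at density
0.0395 provides. Copying that raw density to K = 8 would leave ~73% of
genes in no pathway and the factors unidentified. At K = 8, density 0.3
preserves ~2.4 memberships per gene and ~60 genes per pathway.

`recovery_experiment` runs simulate → fit → permutation per replicate
and scores the identified support (P ≤ 0.05, nonzero coefficient)
against the planted one. Penalties default to
`λ1 = λ2 = 0.3 × lambda_max` per replicate, so the penalty scale tracks
the data scale; coefficient RMSE is computed after aligning per-pathway
signs between the fitted and generating factors (the factorization is
invariant to jointly flipping an X column and its B rows).

What the generator does *not* emulate: empirical gene–gene correlation
beyond the factor structure, heavy-tailed or batch-structured noise,
non-random missingness, and measurement-scale artifacts of real
dose–response summaries. Passing recovery tests therefore demonstrate
correctness of the estimator under its own assumptions, not performance
on any particular experimental panel.

## Problem sizes

Tests and the acceptance script run at desk scale: up to N = 100,
K = 10, G1 = 300, G2 = 30, with T = 100–200 permutations and 10
replicates — sizes chosen so the full suite completes in minutes on one
CPU while exercising every code path at the same N/K/G aspect ratios as
panel-scale data.
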