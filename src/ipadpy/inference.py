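"""Inference: regularization path, permutation P-values and cross-validation.

The fitted drug-pathway coefficients B2 are point estimates; three
complementary tools turn them into ranked, calibrated associations:

* a decreasing-lambda regularization path, recording the order in which
  each coefficient first becomes nonzero (earlier = more important);
* a permutation test that re-fits the model on sample-permuted drug
  response matrices and reports, per coefficient, the fraction of null
  magnitudes at least as large as the observed one;
* entry-level five-fold cross-validation over the observed cells of Y2,
  selecting (lambda1, lambda2) by held-out residual sum of squares with a
  coordinate search (lambda1 first, then lambda2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model_core import (
    FactorModel,
    OmicsDataset,
    PenaltyConfig,
    PriorKnowledge,
    _pg_update_X,
    _replace_y2,
    fit,
    refit_b2,
    update_B1,
)

__all__ = [
    "PathResult",
    "PermutationResult",
    "CVResult",
    "AssociationTable",
    "lambda_max",
    "regularization_path",
    "permutation_test",
    "cross_validate",
    "rank_associations",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# results containers


@dataclass
class PathResult:
    """Regularization path summary.

    ``entry_order[i, j]`` is the 1-based grid index at which coefficient
    (pathway i, drug j) first became nonzero; 0 means it never entered.
    """

    lambda_grid: np.ndarray
    ratio: float
    entry_order: np.ndarray
    support_sizes: np.ndarray
    failed_points: list = field(default_factory=list)


@dataclass
class PermutationResult:
    """Coefficient-wise permutation P-values (each a multiple of 1/T)."""

    pvalues: np.ndarray
    n_permutations: int
    observed_abs: np.ndarray
    seed: int


@dataclass
class CVResult:
    """Held-out RSS surfaces from the coordinate search over (lambda1, lambda2)."""

    lambda1_grid: np.ndarray
    lambda2_grid: np.ndarray
    rss_lambda1: np.ndarray  # len(lambda1_grid) x n_folds, lambda2 at midpoint
    rss_lambda2: np.ndarray  # len(lambda2_grid) x n_folds, lambda1 at best
    best_lambda1: float
    best_lambda2: float
    fold_assignment: np.ndarray  # N x G2, -1 where Y2 unobserved

    @property
    def rss(self) -> np.ndarray:
        return np.vstack([self.rss_lambda1, self.rss_lambda2])


@dataclass
class AssociationTable:
    """Ranked drug-pathway associations (P <= alpha and nonzero coefficient)."""

    table: pd.DataFrame
    identification_rate: float
    alpha: float


# ---------------------------------------------------------------------------
# lambda_max


def _fit_expression_only(ds: OmicsDataset, prior: PriorKnowledge,
                         cfg: PenaltyConfig) -> FactorModel:
    """Alternating fit of (X, B1) on the expression block only (B2 = 0).

    This is the lambda -> infinity limit of the full model: with B2 pinned
    at zero the drug block contributes a constant, so X and B1 solve the
    expression-only factorization.
    """
    rng = np.random.default_rng(cfg.seed)
    from .model_core import project_columns

    X = project_columns(rng.standard_normal((ds.n_samples, prior.n_pathways)))
    B1 = prior.H1.astype(float)
    B2 = np.zeros((prior.n_pathways, ds.n_drugs))
    model = FactorModel(X, B1, B2)
    prev = float(((ds.Y1 - X @ B1) ** 2).sum())
    for it in range(cfg.max_outer_iter):
        model.X = _pg_update_X(ds.Y1, model.B1, model.X, cfg)
        model.B1 = update_B1(ds, model, prior)
        cur = float(((ds.Y1 - model.X @ model.B1) ** 2).sum())
        if abs(prev - cur) <= cfg.tol_rel_obj * max(1.0, abs(prev)):
            break
        prev = cur
    return model


def _masked_xty(ds: OmicsDataset, X: np.ndarray) -> np.ndarray:
    """X^T Y2 using only observed cells (column-wise row restriction)."""
    return X.T @ np.where(ds.mask2, ds.Y2, 0.0)


def lambda_max(ds: OmicsDataset, prior: PriorKnowledge, which: str = "l1",
               cfg: PenaltyConfig | None = None,
               X: np.ndarray | None = None) -> float:
    """Smallest penalty at which B2 = 0 satisfies the optimality condition.

    With X taken from the penalty -> infinity fit, the zero matrix is a
    stationary point of the B2 subproblem iff every entry (l1) or row
    (l21) of 2 X^T Y2 is dominated by the penalty weight.
    """
    if which not in ("l1", "l21"):
        raise ValueError("which must be 'l1' or 'l21'")
    if X is None:
        cfg = cfg or PenaltyConfig()
        X = _fit_expression_only(ds, prior, cfg).X
    M = 2.0 * _masked_xty(ds, X)
    # cells known a priori (H2 = 1) are ridge- not sparsity-penalized and
    # do not constrain the entry threshold
    M = np.where(prior.H2 > 0, 0.0, M)
    if which == "l1":
        return float(np.abs(M).max())
    return float(np.linalg.norm(M, axis=1).max())


# ---------------------------------------------------------------------------
# regularization path


def regularization_path(ds: OmicsDataset, prior: PriorKnowledge,
                        cfg: PenaltyConfig, n_grid: int = 50,
                        ratio: float = 1.0, n_decades: float = 3.0) -> PathResult:
    """Warm-started fits along a decreasing joint (lambda1, lambda2) grid.

    The grid is log-spaced over ``n_decades`` decades below the top value
    ``t_max`` (the element-wise lambda_max, at which the support is empty);
    at grid value t the fit uses lambda1 = t and lambda2 = ratio * t, so
    the two penalties shrink together at a fixed user-chosen ratio.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    null_model = _fit_expression_only(ds, prior, cfg)
    t_max = lambda_max(ds, prior, "l1", cfg, X=null_model.X)
    if t_max == 0.0:
        t_max = 1.0  # degenerate Y2 = 0; any positive grid keeps B2 = 0
    grid = np.geomspace(t_max, t_max / (10.0 ** n_decades), n_grid)
    K, G2 = prior.n_pathways, ds.n_drugs
    entry_order = np.zeros((K, G2), dtype=int)
    support_sizes = np.zeros(n_grid, dtype=int)
    failed: list[int] = []
    warm = null_model
    for g, t in enumerate(grid):
        cfg_g = replace(cfg, lambda1=t, lambda2=ratio * t)
        try:
            warm = fit(ds, prior, cfg_g, init=warm)
        except RuntimeError as exc:  # pragma: no cover - diagnostic path
            logger.warning("path point %d (lambda=%.4g) failed: %s", g, t, exc)
            failed.append(g)
            continue
        nz = warm.B2 != 0
        support_sizes[g] = int(nz.sum())
        newly = nz & (entry_order == 0)
        entry_order[newly] = g + 1
    return PathResult(grid, ratio, entry_order, support_sizes, failed)


# ---------------------------------------------------------------------------
# permutation test


def permutation_test(ds: OmicsDataset, prior: PriorKnowledge, cfg: PenaltyConfig,
                     T: int, seed: int, fast: bool = False,
                     reference: FactorModel | None = None,
                     return_null: bool = False) -> PermutationResult:
    """Permutation P-values for every drug-pathway coefficient.

    Each of the T permutations independently shuffles the sample (row)
    order of Y2 (with its missingness mask), severing the linkage between
    drug response and the expression-driven pathway activities while
    preserving each drug's marginal distribution, then re-fits the model.
    P[i, j] is the fraction of null |B2| values at least as large as the
    observed |B2[i, j]|.  ``fast=True`` freezes X at the reference fit and
    re-estimates only B2 per permutation.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if reference is None:
        reference = fit(ds, prior, cfg)
    observed_abs = np.abs(reference.B2)
    counts = np.zeros_like(observed_abs)
    rng = np.random.default_rng(seed)
    nulls = [] if return_null else None
    for _ in range(T):
        perm = rng.permutation(ds.n_samples)
        ds_perm = _replace_y2(ds, ds.Y2[perm], ds.mask2[perm])
        if fast:
            B2_null = refit_b2(ds_perm, prior, cfg, reference.X)
        else:
            B2_null = fit(ds_perm, prior, cfg).B2
        counts += np.abs(B2_null) >= observed_abs
        if nulls is not None:
            nulls.append(np.abs(B2_null))
    result = PermutationResult(counts / T, T, observed_abs, seed)
    if nulls is not None:
        result.null_abs = np.asarray(nulls)
    return result


# ---------------------------------------------------------------------------
# cross-validation


def _make_folds(ds: OmicsDataset, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Entry-level fold labels over observed Y2 cells; -1 where unobserved."""
    fold = np.full(ds.Y2.shape, -1, dtype=int)
    obs = np.argwhere(ds.mask2)
    order = rng.permutation(len(obs))
    labels = np.arange(len(obs)) % n_folds  # near-equal parts
    fold[obs[order, 0], obs[order, 1]] = labels
    return fold


def _heldout_rss(ds: OmicsDataset, prior: PriorKnowledge, cfg: PenaltyConfig,
                 fold: np.ndarray, n_folds: int) -> np.ndarray:
    """Held-out RSS per fold for one (lambda1, lambda2) setting."""
    rss = np.zeros(n_folds)
    for f in range(n_folds):
        train_mask = ds.mask2 & (fold != f)
        ds_train = _replace_y2(ds, ds.Y2, train_mask)
        model = fit(ds_train, prior, cfg)
        pred = model.X @ model.B2
        held = fold == f
        empty_cols = np.where(train_mask.sum(axis=0) == 0)[0]
        if len(empty_cols):
            logger.warning(
                "fold %d: %d drug column(s) with no training cells excluded",
                f, len(empty_cols))
            held = held.copy()
            held[:, empty_cols] = False
        rss[f] = float(((ds.Y2 - pred)[held] ** 2).sum())
    return rss


def cross_validate(ds: OmicsDataset, prior: PriorKnowledge, cfg: PenaltyConfig,
                   lambda1_grid, lambda2_grid, seed: int,
                   n_folds: int = 5, joint: bool = False) -> CVResult:
    """Entry-level k-fold CV with a coordinate search over the two penalties.

    Observed cells of Y2 are partitioned into ``n_folds`` near-equal parts;
    each part in turn is made missing, the model is fit on the rest, and
    the held-out cells are scored against the prediction X @ B2.  Scans
    lambda1 with lambda2 fixed at its grid midpoint, then lambda2 at the
    chosen lambda1 (``joint=True`` evaluates the full 2-D grid instead).
    """
    lambda1_grid = np.asarray(lambda1_grid, dtype=float)
    lambda2_grid = np.asarray(lambda2_grid, dtype=float)
    if lambda1_grid.size == 0 or lambda2_grid.size == 0:
        raise ValueError("lambda grids must be non-empty")
    rng = np.random.default_rng(seed)
    fold = _make_folds(ds, n_folds, rng)

    if joint:
        rss_all = np.zeros((len(lambda1_grid), len(lambda2_grid), n_folds))
        for i, l1 in enumerate(lambda1_grid):
            for j, l2 in enumerate(lambda2_grid):
                rss_all[i, j] = _heldout_rss(
                    ds, prior, replace(cfg, lambda1=l1, lambda2=l2), fold, n_folds)
        mean = rss_all.mean(axis=2)
        i, j = np.unravel_index(np.argmin(mean), mean.shape)
        return CVResult(lambda1_grid, lambda2_grid,
                        rss_all[:, j, :], rss_all[i, :, :],
                        float(lambda1_grid[i]), float(lambda2_grid[j]), fold)

    l2_mid = float(lambda2_grid[len(lambda2_grid) // 2])
    rss1 = np.zeros((len(lambda1_grid), n_folds))
    for i, l1 in enumerate(lambda1_grid):
        rss1[i] = _heldout_rss(
            ds, prior, replace(cfg, lambda1=float(l1), lambda2=l2_mid), fold, n_folds)
    best1 = float(lambda1_grid[int(np.argmin(rss1.mean(axis=1)))])
    rss2 = np.zeros((len(lambda2_grid), n_folds))
    for j, l2 in enumerate(lambda2_grid):
        rss2[j] = _heldout_rss(
            ds, prior, replace(cfg, lambda1=best1, lambda2=float(l2)), fold, n_folds)
    best2 = float(lambda2_grid[int(np.argmin(rss2.mean(axis=1)))])
    return CVResult(lambda1_grid, lambda2_grid, rss1, rss2, best1, best2, fold)


# ---------------------------------------------------------------------------
# ranking


def rank_associations(model: FactorModel, perm: PermutationResult,
                      path: PathResult | None = None, alpha: float = 0.05,
                      pathway_ids=None, drug_ids=None) -> AssociationTable:
    """Table of identified pairs: P <= alpha and a nonzero coefficient.

    Sorted by P-value then |coefficient|; Benjamini-Hochberg q-values are
    attached for reference but identification uses the raw P cutoff.  The
    identification rate is the identified count over all K*G2 pairs.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    B2 = model.B2
    K, G2 = B2.shape
    pathway_ids = list(pathway_ids) if pathway_ids is not None else [
        f"pathway{i}" for i in range(K)]
    drug_ids = list(drug_ids) if drug_ids is not None else [
        f"drug{j}" for j in range(G2)]
    P = perm.pvalues
    qvals = multipletests(P.ravel(), method="fdr_bh")[1].reshape(P.shape)
    order = path.entry_order if path is not None else np.zeros_like(P, dtype=int)
    keep = (P <= alpha) & (B2 != 0)
    ii, jj = np.nonzero(keep)
    df = pd.DataFrame({
        "drug": [drug_ids[j] for j in jj],
        "pathway": [pathway_ids[i] for i in ii],
        "coefficient": B2[ii, jj],
        "pvalue": P[ii, jj],
        "qvalue": qvals[ii, jj],
        "entry_rank": order[ii, jj],
    })
    df = df.sort_values(
        ["pvalue", "coefficient"],
        key=lambda s: s.abs() if s.name == "coefficient" else s,
        ascending=[True, False],
    ).reset_index(drop=True)
    rate = float(keep.sum()) / (K * G2)
    return AssociationTable(df, rate, alpha)
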