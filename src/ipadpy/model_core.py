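"""Core model: data containers, norms, objective and the alternating fit.

The model jointly factors a sample x gene expression matrix ``Y1`` and a
sample x drug sensitivity matrix ``Y2`` over a shared latent pathway
activity matrix ``X`` (sample x pathway)::

    Y1 = X @ B1 + E1        Y2 = X @ B2 + E2

``B1`` (pathway x gene) is restricted to the support of a binary prior
``H1`` of known gene-pathway memberships; ``B2`` (pathway x drug) is the
quantity of interest and carries a mixed sparsity penalty

    lambda1 * ||B2||_1  +  lambda2 * ||B2||_{2,1}

under the identifiability constraint that every column of ``X`` lies in
the unit Euclidean ball.  ``lambda2 = 0`` recovers the plain lasso-type
decomposition (iPaD); ``lambda1 = 0`` recovers the row-sparse L2,1
variant.  The problem is bi-convex and is solved by block coordinate
descent: an accelerated projected-gradient step for ``X``, restricted
per-column ordinary least squares for ``B1``, and iteratively reweighted
ridge solves (IRLS) for ``B2``.  Missing drug-sensitivity entries are
handled soft-impute style: they never enter the loss, and are filled with
the current prediction ``X @ B2`` only to form the complete matrix needed
by the ``X`` update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

__all__ = [
    "OmicsDataset",
    "PriorKnowledge",
    "FactorModel",
    "PenaltyConfig",
    "l1_norm",
    "l21_norm",
    "lrp_norm",
    "objective",
    "penalized_objective",
    "project_columns",
    "update_X",
    "update_B1",
    "update_B2",
    "impute_missing",
    "fit",
    "refit_b2",
    "method_name",
]

logger = logging.getLogger(__name__)

# Slack allowed on the "objective never increases" guarantee; absorbs the
# hard zero-snapping of small B2 entries and floating point round-off.
TOL_DESCENT = 1e-8


def _as_float_matrix(M, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={M.ndim}")
    return M


# ---------------------------------------------------------------------------
# containers


@dataclass
class OmicsDataset:
    """The observed pair (expression, drug sensitivity) with labels.

    ``Y1`` must be complete; entries of ``Y2`` where ``mask2`` is False are
    treated as unobserved regardless of the stored value.
    """

    Y1: np.ndarray
    Y2: np.ndarray
    mask2: np.ndarray
    sample_ids: list
    gene_ids: list
    drug_ids: list
    #: per-column (mean, sd) recorded when the loader z-scores the data
    standardization: dict | None = None

    def __post_init__(self):
        self.Y1 = _as_float_matrix(self.Y1, "Y1")
        self.Y2 = _as_float_matrix(self.Y2, "Y2")
        self.mask2 = np.asarray(self.mask2, dtype=bool)
        if not np.all(np.isfinite(self.Y1)):
            raise ValueError("Y1 must not contain missing or non-finite entries")
        if self.Y1.shape[0] != self.Y2.shape[0]:
            raise ValueError("Y1 and Y2 must have the same number of samples")
        if self.mask2.shape != self.Y2.shape:
            raise ValueError("mask2 must have the shape of Y2")
        n, g1 = self.Y1.shape
        g2 = self.Y2.shape[1]
        if n < 2 or g1 < 1 or g2 < 1:
            raise ValueError("need N >= 2, G1 >= 1 and G2 >= 1")
        for ids, size, what in (
            (self.sample_ids, n, "sample_ids"),
            (self.gene_ids, g1, "gene_ids"),
            (self.drug_ids, g2, "drug_ids"),
        ):
            if len(ids) != size:
                raise ValueError(f"{what} has length {len(ids)}, expected {size}")
            if len(set(ids)) != len(ids):
                raise ValueError(f"{what} must be unique")
        if not np.all(np.isfinite(self.Y2[self.mask2])):
            raise ValueError("observed entries of Y2 must be finite")

    @property
    def n_samples(self) -> int:
        return self.Y1.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Y1.shape[1]

    @property
    def n_drugs(self) -> int:
        return self.Y2.shape[1]


@dataclass
class PriorKnowledge:
    """Binary membership indicators: ``H1`` pathway x gene, ``H2`` pathway x drug.

    ``H2`` may be all zero (no prior drug-pathway knowledge, the common
    setting); any ``H2[i, j] = 1`` entry is treated as an already-known
    association and ridge- rather than sparsity-penalized.
    """

    H1: np.ndarray
    H2: np.ndarray
    pathway_ids: list

    def __post_init__(self):
        self.H1 = np.asarray(self.H1)
        self.H2 = np.asarray(self.H2)
        for H, name in ((self.H1, "H1"), (self.H2, "H2")):
            if H.ndim != 2:
                raise ValueError(f"{name} must be 2-D")
            if not np.isin(H, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0 or 1")
        self.H1 = self.H1.astype(np.int8)
        self.H2 = self.H2.astype(np.int8)
        if self.H1.shape[0] != self.H2.shape[0]:
            raise ValueError("H1 and H2 must agree on the number of pathways")
        if len(self.pathway_ids) != self.H1.shape[0]:
            raise ValueError("pathway_ids length must equal the number of H rows")
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("pathway_ids must be unique")

    @property
    def n_pathways(self) -> int:
        return self.H1.shape[0]

    def density(self, which: str = "H1") -> float:
        H = self.H1 if which == "H1" else self.H2
        return float(H.sum()) / H.size


@dataclass
class PenaltyConfig:
    """Penalty weights and solver controls.

    ``zero_threshold`` is relative: after each B2 update, entries below
    ``zero_threshold`` times the larger of max|B2| and the natural
    single-coefficient scale of the data are snapped to exactly zero, so
    the reported support is unambiguous even when the whole solution is
    (correctly) zero and only approached geometrically.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    step_mu: float | str = "auto"
    max_outer_iter: int = 500
    max_inner_iter: int = 100
    tol_rel_obj: float = 1e-6
    eps_reweight: float = 1e-10
    zero_threshold: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be non-negative")
        for v, name in (
            (self.tol_rel_obj, "tol_rel_obj"),
            (self.eps_reweight, "eps_reweight"),
            (self.zero_threshold, "zero_threshold"),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.step_mu != "auto" and float(self.step_mu) <= 0:
            raise ValueError("step_mu must be positive or 'auto'")


@dataclass
class FactorModel:
    """A fitted (or ground-truth) triplet (X, B1, B2)."""

    X: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iter: int = 0
    converged: bool = False

    def copy(self) -> "FactorModel":
        return FactorModel(
            self.X.copy(),
            self.B1.copy(),
            self.B2.copy(),
            np.array(self.objective_trace, copy=True),
            self.n_iter,
            self.converged,
        )


# ---------------------------------------------------------------------------
# norms


def _check_finite(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    return M


def l1_norm(M) -> float:
    """Element-wise L1 norm: the sum of absolute entries."""
    return float(np.abs(_check_finite(M)).sum())


def l21_norm(M) -> float:
    """L2,1 norm: the sum of Euclidean norms of the rows."""
    M = _check_finite(M)
    return float(np.linalg.norm(M, axis=-1).sum())


def lrp_norm(M, r: float = 2.0, p: float = 1.0) -> float:
    """General Lr,p norm: the p-norm of the vector of row r-norms.

    Utility only; the model objective uses ``l1_norm`` and ``l21_norm``.
    """
    M = _check_finite(M)
    rows = (np.abs(M) ** r).sum(axis=-1) ** (1.0 / r)
    return float((rows**p).sum() ** (1.0 / p))


# ---------------------------------------------------------------------------
# objective and feasibility


def masked_rss(ds: OmicsDataset, model: FactorModel) -> float:
    """Residual sum of squares over Y1 and the observed cells of Y2."""
    R1 = ds.Y1 - model.X @ model.B1
    R2 = ds.Y2 - model.X @ model.B2
    return float((R1 * R1).sum() + (R2 * R2)[ds.mask2].sum())


def objective(ds: OmicsDataset, model: FactorModel, cfg: PenaltyConfig) -> float:
    """Penalized objective; missing Y2 cells are excluded from the loss."""
    if model.X.shape != (ds.n_samples, model.B1.shape[0]):
        raise ValueError("X shape does not conform to the dataset")
    if model.B1.shape[1] != ds.n_genes or model.B2.shape[1] != ds.n_drugs:
        raise ValueError("B1/B2 shapes do not conform to the dataset")
    pen = 0.0
    if cfg.lambda1:
        pen += cfg.lambda1 * l1_norm(model.B2)
    if cfg.lambda2:
        pen += cfg.lambda2 * l21_norm(model.B2)
    return masked_rss(ds, model) + pen


def penalized_objective(ds: OmicsDataset, model: FactorModel,
                        prior: PriorKnowledge, cfg: PenaltyConfig) -> float:
    """The objective the fit actually minimizes, honoring the H2 split.

    Coefficients at cells flagged known by H2 carry a ridge penalty
    (lambda2 * b^2) instead of the sparsity penalties; the L1 and row-wise
    L2,1 terms run over the unknown (H2 = 0) cells only.  With an all-zero
    H2 this coincides with :func:`objective`.
    """
    B2 = model.B2
    unknown = prior.H2 == 0
    pen = 0.0
    if cfg.lambda1:
        pen += cfg.lambda1 * float(np.abs(np.where(unknown, B2, 0.0)).sum())
    if cfg.lambda2:
        rows = np.sqrt((np.where(unknown, B2, 0.0) ** 2).sum(axis=1))
        pen += cfg.lambda2 * float(rows.sum())
        pen += cfg.lambda2 * float((B2[~unknown] ** 2).sum())
    return masked_rss(ds, model) + pen


def project_columns(X) -> np.ndarray:
    """Rescale every column with Euclidean norm > 1 back onto the unit ball."""
    X = np.asarray(X, dtype=float).copy()
    norms = np.linalg.norm(X, axis=0)
    over = norms > 1.0
    if over.any():
        X[:, over] /= norms[over]
    return X


# ---------------------------------------------------------------------------
# block updates


def _pg_update_X(Y: np.ndarray, B: np.ndarray, X0: np.ndarray,
                 cfg: PenaltyConfig) -> np.ndarray:
    """Accelerated projected gradient for min_X ||Y - XB||_F^2 on unit columns.

    Nesterov momentum with a restart whenever the objective would rise
    (projection breaks the usual monotonicity guarantee); the automatic
    step is 1 / (2 ||B B^T||_2), the inverse gradient-Lipschitz constant.
    """
    G = B @ B.T
    C = Y @ B.T
    L = float(scipy.linalg.norm(G, 2)) if G.size else 0.0
    if L <= 1e-300:
        return X0.copy()  # loss independent of X
    mu = 1.0 / (2.0 * L) if cfg.step_mu == "auto" else float(cfg.step_mu)

    def f(X):
        return float((X * (X @ G)).sum() - 2.0 * (X * C).sum())

    Xc = X0.copy()
    Z = X0.copy()
    fc = f(Xc)
    t = 1.0
    for _ in range(cfg.max_inner_iter):
        grad = 2.0 * (Z @ G - C)
        if not np.all(np.isfinite(grad)):
            raise RuntimeError(
                "non-finite gradient in the X update; step_mu is likely too "
                f"large (step_mu={cfg.step_mu!r})"
            )
        Xn = project_columns(Z - mu * grad)
        fn = f(Xn)
        if not np.isfinite(fn):
            raise RuntimeError(
                "non-finite objective in the X update; step_mu is too large "
                f"(step_mu={cfg.step_mu!r})"
            )
        if fn > fc:
            # momentum restart: plain projected step from the last iterate
            t = 1.0
            Xn = project_columns(Xc - mu * 2.0 * (Xc @ G - C))
            if not np.all(np.isfinite(Xn)):
                raise RuntimeError(
                    f"non-finite X iterate; step_mu={cfg.step_mu!r} is too large"
                )
            fn = f(Xn)
            if fn > fc:  # cannot happen for mu <= 1/(2L); user-set steps can
                Xn, fn = Xc, fc
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Z = Xn + ((t - 1.0) / t_next) * (Xn - Xc)
        done = abs(fc - fn) <= cfg.tol_rel_obj * max(1.0, abs(fc))
        Xc, fc, t = Xn, fn, t_next
        if done:
            break
    return Xc


def impute_missing(ds: OmicsDataset, model: FactorModel) -> np.ndarray:
    """Complete copy of Y2 with unobserved cells filled by X @ B2."""
    pred = model.X @ model.B2
    return np.where(ds.mask2, ds.Y2, pred)


def update_X(ds: OmicsDataset, model: FactorModel, cfg: PenaltyConfig) -> np.ndarray:
    """One inner pass of accelerated projected gradient on X.

    Missing Y2 cells are soft-imputed with the current prediction first, so
    the complete-data quadratic majorizes the masked loss at the current X
    and descent on it implies descent on the true objective.
    """
    Y = np.hstack([ds.Y1, impute_missing(ds, model)])
    B = np.hstack([model.B1, model.B2])
    return _pg_update_X(Y, B, model.X, cfg)


def update_B1(ds: OmicsDataset, model: FactorModel, prior: PriorKnowledge) -> np.ndarray:
    """Exact B1 update: per-gene OLS restricted to the H1 support.

    Genes sharing a support pattern are solved together from the normal
    equations, batched over patterns of equal support size; a
    rank-deficient restricted design falls back to a minimum-norm
    least-squares solve with a warning.
    """
    X = model.X
    K = prior.n_pathways
    B1 = np.zeros((K, ds.n_genes))
    Gram = X.T @ X
    C = X.T @ ds.Y1
    patterns: dict[bytes, list[int]] = {}
    supp_mask = prior.H1 > 0
    for q in range(ds.n_genes):
        patterns.setdefault(supp_mask[:, q].tobytes(), []).append(q)
    by_size: dict[int, list[tuple[np.ndarray, list[int]]]] = {}
    for key, cols in patterns.items():
        s = np.frombuffer(key, dtype=bool)
        if not s.any():
            continue  # pathway prior excludes this gene everywhere
        by_size.setdefault(int(s.sum()), []).append((np.where(s)[0], cols))
    for size, group in by_size.items():
        m = len(group)
        wmax = max(len(cols) for _, cols in group)
        A = np.empty((m, size, size))
        R = np.zeros((m, size, wmax))
        for g, (idx, cols) in enumerate(group):
            A[g] = Gram[np.ix_(idx, idx)]
            R[g, :, : len(cols)] = C[np.ix_(idx, cols)]
        try:
            sol = np.linalg.solve(A, R)
        except np.linalg.LinAlgError:
            for idx, cols in group:
                try:
                    B1[np.ix_(idx, cols)] = scipy.linalg.solve(
                        Gram[np.ix_(idx, idx)], C[np.ix_(idx, cols)],
                        assume_a="pos")
                except scipy.linalg.LinAlgError:
                    logger.warning(
                        "rank-deficient restricted design in B1 update "
                        "(support size %d); using minimum-norm least squares",
                        len(idx))
                    B1[np.ix_(idx, cols)] = np.linalg.lstsq(
                        X[:, idx], ds.Y1[:, cols], rcond=None)[0]
            continue
        for g, (idx, cols) in enumerate(group):
            B1[np.ix_(idx, cols)] = sol[g, :, : len(cols)]
    return B1


def _solve_weighted_ridge(G: np.ndarray, c: np.ndarray, w: np.ndarray,
                          X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve (G + diag(w)) b = c, falling back to augmented least squares."""
    A = G.copy()
    A[np.diag_indices_from(A)] += w
    try:
        return np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        logger.warning(
            "singular system in B2 update; using minimum-norm least squares"
        )
        aug = np.vstack([X, np.diag(np.sqrt(np.maximum(w, 0.0)))])
        rhs = np.concatenate([y, np.zeros(len(w))])
        return np.linalg.lstsq(aug, rhs, rcond=None)[0]


def update_B2(ds: OmicsDataset, model: FactorModel, prior: PriorKnowledge,
              cfg: PenaltyConfig) -> np.ndarray:
    """B2 update by iteratively reweighted ridge solves (matrix IRLS).

    Given X, the B2 subproblem decomposes over drug columns q,

        ||y_q - X b_q||^2  +  lambda1 ||b_q||_1  +  lambda2 (L2,1 share),

    with the L2,1 term coupling columns through the row norms of B2 (over
    the H2 = 0 cells that carry the sparsity penalties); only the observed
    rows of y_q enter the loss.  Coordinates flagged known by H2 are
    ridge-penalized with weight lambda2 instead.  Each sweep solves, for
    every column at once, a ridge system with diagonal weights

        w_iq = lambda1 / (2 |B2_iq| + eps)  +  lambda2 / (2 ||row_i|| + eps)

    built from the current B2.  The weighted quadratic majorizes the exact
    penalty for any eps > 0 (AM-GM), so the objective never increases, and
    the sweeps are iterated to a fixed point -- the minimizer of the convex
    B2 subproblem, at which every column is per-column optimal.  Entries
    below the (relative) zero threshold are snapped to exact zeros at the
    end.
    """
    X = model.X
    K = prior.n_pathways
    G2 = ds.n_drugs
    B2 = model.B2.copy()
    eps = cfg.eps_reweight
    l1, l2 = cfg.lambda1, cfg.lambda2
    Gram_full = X.T @ X
    C_full = X.T @ np.where(ds.mask2, ds.Y2, 0.0)
    known_all = prior.H2 > 0
    unknown_all = ~known_all

    # group drug columns by missingness pattern so each IRLS sweep is one
    # stacked solve; fully-observed columns share the precomputed Gram
    groups: dict[bytes, list[int]] = {}
    for q in range(G2):
        groups.setdefault(ds.mask2[:, q].tobytes(), []).append(q)
    solvable: list[int] = []
    A_base = np.empty((G2, K, K))
    c_all = np.empty((K, G2))
    for key, qs in groups.items():
        rows = np.frombuffer(key, dtype=bool)
        if not rows.any():
            B2[:, qs] = 0.0  # no observations for these drugs
            continue
        solvable.extend(qs)
        if rows.all():
            A_base[qs] = Gram_full
            c_all[:, qs] = C_full[:, qs]
        else:
            Xr = X[rows]
            A_base[qs] = Xr.T @ Xr
            c_all[:, qs] = Xr.T @ ds.Y2[np.ix_(np.where(rows)[0], qs)]
    if not solvable:
        return B2
    cols = np.asarray(sorted(solvable))
    diag = np.arange(K)

    static = (l1 == 0.0 and l2 == 0.0) or bool(known_all.all())
    for _ in range(1 if static else cfg.max_inner_iter):
        W = np.zeros((K, G2))
        W[known_all] = l2
        if unknown_all.any():
            wu = np.zeros((K, G2))
            if l1:
                wu += l1 / (2.0 * np.abs(B2) + eps)
            if l2:
                Bu = np.where(unknown_all, B2, 0.0)
                r = np.sqrt((Bu * Bu).sum(axis=1))
                wu += (l2 / (2.0 * r + eps))[:, None]
            W[unknown_all] = wu[unknown_all]
        A = A_base[cols].copy()
        A[:, diag, diag] += W[:, cols].T
        try:
            sol = np.linalg.solve(A, c_all[:, cols].T[:, :, None])[:, :, 0].T
        except np.linalg.LinAlgError:
            sol = np.empty((K, len(cols)))
            for j, q in enumerate(cols):
                rows = ds.mask2[:, q]
                sol[:, j] = _solve_weighted_ridge(
                    A_base[q], c_all[:, q], W[:, q], X[rows], ds.Y2[rows, q])
        delta = np.abs(sol - B2[:, cols])
        B2[:, cols] = sol
        # element-wise relative test: every coefficient must have settled
        # on its own scale -- coefficients escaping the zero warm start
        # grow geometrically from ~eps and a matrix-norm test would let
        # already-converged large entries mask them
        if (delta <= cfg.tol_rel_obj * (np.abs(sol) + eps)).all():
            break

    # Snap scale: max |B2|, floored by the natural single-coefficient scale
    # of the data so that an all-zero solution approached geometrically
    # (entries ~ eps) is recognized as exactly zero.
    diag_scale = max(1.0, float(np.abs(np.diag(Gram_full)).max())) if K else 1.0
    s_data = float(np.abs(C_full).max()) / diag_scale if C_full.size else 0.0
    m = max(float(np.abs(B2).max()), s_data)
    if m > 0:
        B2[np.abs(B2) < cfg.zero_threshold * m] = 0.0
    return B2


# ---------------------------------------------------------------------------
# alternating fit


def method_name(cfg: PenaltyConfig) -> str:
    """Which member of the model family a penalty configuration selects."""
    if cfg.lambda1 > 0 and cfg.lambda2 == 0:
        return "iPaD"
    if cfg.lambda1 == 0 and cfg.lambda2 > 0:
        return "L21-iPaD"
    if cfg.lambda1 == 0 and cfg.lambda2 == 0:
        return "unpenalized"
    return "L1L21-iPaD"


def _init_model(ds: OmicsDataset, prior: PriorKnowledge,
                cfg: PenaltyConfig) -> FactorModel:
    rng = np.random.default_rng(cfg.seed)
    X = project_columns(rng.standard_normal((ds.n_samples, prior.n_pathways)))
    B1 = prior.H1.astype(float)
    B2 = np.zeros((prior.n_pathways, ds.n_drugs))
    return FactorModel(X, B1, B2)


def fit(ds: OmicsDataset, prior: PriorKnowledge, cfg: PenaltyConfig,
        init: FactorModel | None = None) -> FactorModel:
    """Alternating block-coordinate fit.

    Starts from ``B1 = H1``, ``B2 = 0`` and a random feasible ``X`` seeded
    by ``cfg.seed`` (or from ``init``, for warm starts along a
    regularization path), then cycles X -> B1 -> B2 updates until the
    relative objective change drops below ``cfg.tol_rel_obj``.  Raises if
    the objective increases beyond tolerance for three consecutive outer
    iterations, which indicates a broken step size.
    """
    if prior.H1.shape[1] != ds.n_genes or prior.H2.shape[1] != ds.n_drugs:
        raise ValueError("prior H1/H2 shapes do not conform to the dataset")
    model = _init_model(ds, prior, cfg) if init is None else init.copy()
    obj = penalized_objective(ds, model, prior, cfg)
    trace = [obj]
    n_bad = 0
    converged = False
    it = 0
    for it in range(1, cfg.max_outer_iter + 1):
        model.X = update_X(ds, model, cfg)
        model.B1 = update_B1(ds, model, prior)
        model.B2 = update_B2(ds, model, prior, cfg)
        new_obj = penalized_objective(ds, model, prior, cfg)
        trace.append(new_obj)
        slack = TOL_DESCENT * max(1.0, abs(obj))
        if new_obj > obj + slack:
            n_bad += 1
            if n_bad >= 3:
                raise RuntimeError(
                    "objective increased for 3 consecutive outer iterations "
                    f"(last {obj:.6g} -> {new_obj:.6g}); check step_mu"
                )
        else:
            n_bad = 0
        if abs(obj - new_obj) <= cfg.tol_rel_obj * max(1.0, abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    model.objective_trace = np.asarray(trace)
    model.n_iter = it
    model.converged = converged
    return model


def refit_b2(ds: OmicsDataset, prior: PriorKnowledge, cfg: PenaltyConfig,
             X: np.ndarray, max_sweeps: int = 50) -> np.ndarray:
    """Re-estimate B2 only, with the pathway activities X frozen.

    Used by the fast permutation mode: repeats the IRLS update until B2
    stabilizes, starting from zero.
    """
    model = FactorModel(X, np.zeros((prior.n_pathways, ds.n_genes)),
                        np.zeros((prior.n_pathways, ds.n_drugs)))
    for _ in range(max_sweeps):
        B2_new = update_B2(ds, model, prior, cfg)
        delta = np.linalg.norm(B2_new - model.B2)
        model.B2 = B2_new
        if delta <= cfg.tol_rel_obj * max(1.0, np.linalg.norm(B2_new)):
            break
    return model.B2


def _replace_y2(ds: OmicsDataset, Y2: np.ndarray, mask2: np.ndarray) -> OmicsDataset:
    """Dataset with Y2/mask2 swapped out (labels and Y1 shared)."""
    return OmicsDataset(ds.Y1, Y2, mask2, ds.sample_ids, ds.gene_ids, ds.drug_ids)


# re-exported for dataclass convenience in sibling modules
config_replace = replace
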