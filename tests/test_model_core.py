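"""Unit and property tests for the core decomposition machinery."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import ipadpy as ip
from ipadpy.model_core import (
    FactorModel,
    PenaltyConfig,
    _init_model,
    l1_norm,
    l21_norm,
    lrp_norm,
    masked_rss,
    objective,
    penalized_objective,
    project_columns,
)

from oracles import b2_coordinate_oracle, b2_subproblem_objective, pg_update_x


# ---------------------------------------------------------------------------
# norms


@pytest.mark.parametrize("M,expected", [
    ([[1, -2], [0, 3]], 6.0),
    (np.zeros((3, 3)), 0.0),
])
def test_l1_norm_examples(M, expected):
    assert l1_norm(M) == expected


@pytest.mark.parametrize("M,expected", [
    ([[3, 4], [0, 0]], 5.0),
    (np.eye(2), 2.0),
])
def test_l21_norm_examples(M, expected):
    assert l21_norm(M) == pytest.approx(expected)


def test_norms_match_elementwise_loops():
    """Vectorized norms agree with explicit double loops on random input."""
    M = np.random.default_rng(0).standard_normal((3, 3))
    assert l1_norm(M) == pytest.approx(
        sum(abs(M[i, j]) for i in range(3) for j in range(3)))
    M = np.random.default_rng(1).standard_normal((4, 2))
    assert l21_norm(M) == pytest.approx(
        sum(np.sqrt(sum(M[i, j] ** 2 for j in range(2))) for i in range(4)))


def test_lrp_norm_reduces_to_l1_and_l21():
    M = np.random.default_rng(2).standard_normal((4, 3))
    assert lrp_norm(M, r=1, p=1) == pytest.approx(l1_norm(M))
    assert lrp_norm(M, r=2, p=1) == pytest.approx(l21_norm(M))


@pytest.mark.parametrize("bad", [[[np.nan, 1]], [[np.inf, 0]]])
def test_norms_reject_non_finite(bad):
    with pytest.raises(ValueError):
        l1_norm(bad)
    with pytest.raises(ValueError):
        l21_norm(bad)


# ---------------------------------------------------------------------------
# projection


def test_project_columns_examples():
    X = np.array([[0.6], [0.8]])
    np.testing.assert_array_equal(project_columns(X), X)  # norm 1: untouched
    X = np.array([[3.0], [4.0]])
    np.testing.assert_allclose(project_columns(X), [[0.6], [0.8]])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(arrays(float, (5, 3), elements=st.floats(-10, 10)))
def test_project_columns_feasible_and_idempotent(X):
    P = project_columns(X)
    norms = np.linalg.norm(P, axis=0)
    assert (norms <= 1.0 + 1e-12).all()
    np.testing.assert_allclose(project_columns(P), P, atol=1e-15)
    # interior columns are untouched
    inside = np.linalg.norm(X, axis=0) <= 1.0
    np.testing.assert_array_equal(P[:, inside], np.asarray(X, float)[:, inside])


# ---------------------------------------------------------------------------
# objective


def test_objective_zero_model_is_zero(small_sim):
    ds, prior, _ = small_sim
    K = prior.n_pathways
    ds0 = ip.OmicsDataset(np.zeros_like(ds.Y1), np.zeros_like(ds.Y2),
                          ds.mask2, ds.sample_ids, ds.gene_ids, ds.drug_ids)
    model = FactorModel(np.zeros((ds.n_samples, K)),
                        np.zeros((K, ds.n_genes)), np.zeros((K, ds.n_drugs)))
    assert objective(ds0, model, PenaltyConfig(lambda1=1, lambda2=1)) == 0.0


def test_objective_matches_term_by_term_recomputation(masked_sim):
    ds, prior, truth = masked_sim
    cfg = PenaltyConfig(lambda1=0.7, lambda2=0.3, seed=2)
    model = FactorModel(truth.X, truth.B1, truth.B2)
    manual = 0.0
    R1 = ds.Y1 - truth.X @ truth.B1
    manual += (R1 ** 2).sum()
    R2 = ds.Y2 - truth.X @ truth.B2
    manual += (R2[ds.mask2] ** 2).sum()
    manual += 0.7 * np.abs(truth.B2).sum()
    manual += 0.3 * np.linalg.norm(truth.B2, axis=1).sum()
    assert objective(ds, model, cfg) == pytest.approx(manual, rel=1e-12)
    # with zero penalties, only the masked residual remains
    cfg0 = PenaltyConfig(lambda1=0.0, lambda2=0.0)
    assert objective(ds, model, cfg0) == pytest.approx(masked_rss(ds, model))


def test_objective_shape_mismatch_raises(small_sim):
    ds, prior, truth = small_sim
    bad = FactorModel(truth.X[:, :-1], truth.B1, truth.B2)
    with pytest.raises(ValueError):
        objective(ds, bad, PenaltyConfig())


# ---------------------------------------------------------------------------
# update_X


def test_update_x_fixed_point_at_exact_solution(small_sim):
    ds, prior, truth = small_sim
    spec0 = ip.SimulationSpec(N=30, K=4, G1=50, G2=8, h1_density=0.4,
                              h2_density=0.0, noise_sd=0.0,
                              missing_rate2=0.0, seed=42)
    ds0, prior0, truth0 = ip.simulate(spec0)
    model = FactorModel(truth0.X, truth0.B1, truth0.B2)
    X_new = ip.update_X(ds0, model, PenaltyConfig())
    np.testing.assert_allclose(X_new, truth0.X, atol=1e-12)


def test_update_x_k1_recovers_unit_column():
    """K=1, B=(1), Y one unit-norm column: X converges to that column."""
    rng = np.random.default_rng(10)
    y = rng.standard_normal(20)
    y /= np.linalg.norm(y)
    Y = y[:, None]
    B = np.array([[1.0]])
    X0 = project_columns(rng.standard_normal((20, 1)))
    cfg = PenaltyConfig(max_inner_iter=500)
    X = pg_update_x(Y, B, X0)  # oracle
    np.testing.assert_allclose(X[:, 0], y, atol=1e-6)
    from ipadpy.model_core import _pg_update_X
    X2 = _pg_update_X(Y, B, X0, cfg)
    np.testing.assert_allclose(X2[:, 0], y, atol=1e-5)


def test_update_x_matches_long_run_projected_gradient():
    rng = np.random.default_rng(4)
    N, K, G = 6, 4, 10
    Y = rng.standard_normal((N, G))
    B = rng.standard_normal((K, G))
    X0 = project_columns(rng.standard_normal((N, K)))
    cfg = PenaltyConfig(max_inner_iter=2000, tol_rel_obj=1e-14)
    from ipadpy.model_core import _pg_update_X
    X = _pg_update_X(Y, B, X0, cfg)
    X_ref = pg_update_x(Y, B, X0, n_iter=100000, tol=1e-16)
    f = ((Y - X @ B) ** 2).sum()
    f_ref = ((Y - X_ref @ B) ** 2).sum()
    assert abs(f - f_ref) <= 1e-6 * max(1.0, f_ref)


def test_update_x_bad_step_raises(small_sim):
    ds, prior, truth = small_sim
    model = FactorModel(truth.X, truth.B1, truth.B2)
    with pytest.raises(RuntimeError, match="step_mu"):
        ip.update_X(ds, model, PenaltyConfig(step_mu=1e308, max_inner_iter=50))


# ---------------------------------------------------------------------------
# update_B1


def test_update_b1_zero_support_column_stays_zero(small_sim):
    ds, prior, truth = small_sim
    H1 = prior.H1.copy()
    H1[:, 0] = 0
    prior0 = ip.PriorKnowledge(H1, prior.H2, prior.pathway_ids)
    model = FactorModel(truth.X, truth.B1, truth.B2)
    B1 = ip.update_B1(ds, model, prior0)
    assert (B1[:, 0] == 0).all()
    assert (B1[H1 == 0] == 0).all()


def test_update_b1_orthonormal_square_x_gives_xty():
    rng = np.random.default_rng(11)
    N = K = 5
    Q, _ = np.linalg.qr(rng.standard_normal((N, N)))
    Y1 = rng.standard_normal((N, 7))
    ds = ip.OmicsDataset(Y1, np.zeros((N, 1)), np.ones((N, 1), bool),
                         [f"s{i}" for i in range(N)],
                         [f"g{j}" for j in range(7)], ["d0"])
    prior = ip.PriorKnowledge(np.ones((K, 7), int), np.zeros((K, 1), int),
                              [f"p{i}" for i in range(K)])
    model = FactorModel(Q, np.zeros((K, 7)), np.zeros((K, 1)))
    B1 = ip.update_B1(ds, model, prior)
    np.testing.assert_allclose(B1, Q.T @ Y1, atol=1e-10)


def test_update_b1_matches_normal_equation_oracle():
    rng = np.random.default_rng(5)
    N, K, G1 = 5, 3, 2
    X = project_columns(rng.standard_normal((N, K)))
    Y1 = rng.standard_normal((N, G1))
    H1 = np.array([[1, 0], [1, 1], [0, 1]], dtype=int)
    ds = ip.OmicsDataset(Y1, np.zeros((N, 1)), np.ones((N, 1), bool),
                         [f"s{i}" for i in range(N)], ["gA", "gB"], ["d0"])
    prior = ip.PriorKnowledge(H1, np.zeros((K, 1), int), ["p0", "p1", "p2"])
    model = FactorModel(X, np.zeros((K, G1)), np.zeros((K, 1)))
    B1 = ip.update_B1(ds, model, prior)
    for q in range(G1):
        s = H1[:, q] > 0
        Xs = X[:, s]
        expected = np.linalg.inv(Xs.T @ Xs) @ Xs.T @ Y1[:, q]
        np.testing.assert_allclose(B1[s, q], expected, atol=1e-10)
        assert (B1[~s, q] == 0).all()


# ---------------------------------------------------------------------------
# update_B2


def test_update_b2_unpenalized_equals_least_squares(small_sim):
    ds, prior, truth = small_sim
    K = prior.n_pathways
    model = FactorModel(truth.X, truth.B1, np.zeros((K, ds.n_drugs)))
    cfg = PenaltyConfig(lambda1=0.0, lambda2=0.0)
    B2 = ip.update_B2(ds, model, prior, cfg)
    expected = np.linalg.lstsq(truth.X, ds.Y2, rcond=None)[0]
    np.testing.assert_allclose(B2, expected, atol=1e-8)


def test_update_b2_ridge_identity_halves_y2():
    """With X = I, all-known prior and lambda2 = 1, B2 = Y2 / 2."""
    rng = np.random.default_rng(12)
    N = K = 6
    G2 = 4
    Y2 = rng.standard_normal((N, G2))
    ds = ip.OmicsDataset(rng.standard_normal((N, 3)), Y2,
                         np.ones((N, G2), bool),
                         [f"s{i}" for i in range(N)],
                         [f"g{j}" for j in range(3)],
                         [f"d{j}" for j in range(G2)])
    prior = ip.PriorKnowledge(np.ones((K, 3), int), np.ones((K, G2), int),
                              [f"p{i}" for i in range(K)])
    model = FactorModel(np.eye(N), np.zeros((K, 3)), np.zeros((K, G2)))
    cfg = PenaltyConfig(lambda1=0.0, lambda2=1.0, zero_threshold=1e-300)
    B2 = ip.update_B2(ds, model, prior, cfg)
    np.testing.assert_allclose(B2, Y2 / 2.0, atol=1e-12)


def test_update_b2_matches_convex_solver_oracle():
    """Mixed-penalty update reaches the B2 subproblem optimum."""
    rng = np.random.default_rng(6)
    for trial in range(3):
        spec = ip.SimulationSpec(N=12, K=3, G1=20, G2=2, h1_density=0.5,
                                 h2_density=0.0, missing_rate2=0.1,
                                 seed=600 + trial)
        ds, prior, _ = ip.simulate(spec)
        X = project_columns(rng.standard_normal((12, 3)))
        cfg = PenaltyConfig(lambda1=0.3, lambda2=0.2, max_inner_iter=500,
                            tol_rel_obj=1e-12)
        model = FactorModel(X, np.zeros((3, ds.n_genes)), np.zeros((3, 2)))
        mine = ip.update_B2(ds, model, prior, cfg)
        ref = b2_coordinate_oracle(ds, X, prior, 0.3, 0.2)
        o_mine = b2_subproblem_objective(ds, X, mine, prior, 0.3, 0.2)
        o_ref = b2_subproblem_objective(ds, X, ref, prior, 0.3, 0.2)
        assert o_mine <= o_ref + 1e-5 * max(1.0, o_ref)


# ---------------------------------------------------------------------------
# impute_missing


def test_impute_missing_cases(masked_sim):
    ds, prior, truth = masked_sim
    model = FactorModel(truth.X, truth.B1, truth.B2)
    # fully observed: identical to Y2
    ds_full = ip.OmicsDataset(ds.Y1, ds.Y2, np.ones_like(ds.mask2),
                              ds.sample_ids, ds.gene_ids, ds.drug_ids)
    np.testing.assert_array_equal(ip.impute_missing(ds_full, model), ds.Y2)
    # fully missing: exactly the prediction
    ds_none = ip.OmicsDataset(ds.Y1, ds.Y2, np.zeros_like(ds.mask2),
                              ds.sample_ids, ds.gene_ids, ds.drug_ids)
    np.testing.assert_array_equal(ip.impute_missing(ds_none, model),
                                  truth.X @ truth.B2)
    # mixed: observed cells bit-identical, missing cells predicted
    out = ip.impute_missing(ds, model)
    np.testing.assert_array_equal(out[ds.mask2], ds.Y2[ds.mask2])
    np.testing.assert_array_equal(out[~ds.mask2],
                                  (truth.X @ truth.B2)[~ds.mask2])


# ---------------------------------------------------------------------------
# fit


def test_fit_noiseless_data_reaches_tiny_residual():
    # Bi-convex alternation can stall on unlucky noiseless instances (a
    # known limitation of alternating least squares); this instance is one
    # where the alternation reaches the exact factorization.
    spec = ip.SimulationSpec(N=40, K=4, G1=60, G2=8, h1_density=0.4,
                             h2_density=0.0, noise_sd=0.0,
                             missing_rate2=0.0, seed=22)
    ds, prior, truth = ip.simulate(spec)
    cfg = PenaltyConfig(lambda1=0.0, lambda2=0.0, seed=3,
                        tol_rel_obj=1e-10, max_outer_iter=1000)
    model = ip.fit(ds, prior, cfg)
    total = (ds.Y1 ** 2).sum() + (ds.Y2 ** 2).sum()
    assert masked_rss(ds, model) < 1e-6 * total


def test_fit_huge_penalty_zeroes_b2(small_sim):
    ds, prior, _ = small_sim
    model = ip.fit(ds, prior, PenaltyConfig(lambda1=1e6, lambda2=1e6, seed=4))
    assert not (model.B2 != 0).any()


def test_fit_is_deterministic(small_sim, quick_cfg):
    ds, prior, _ = small_sim
    m1 = ip.fit(ds, prior, quick_cfg)
    m2 = ip.fit(ds, prior, quick_cfg)
    np.testing.assert_array_equal(m1.X, m2.X)
    np.testing.assert_array_equal(m1.B1, m2.B1)
    np.testing.assert_array_equal(m1.B2, m2.B2)
    np.testing.assert_array_equal(m1.objective_trace, m2.objective_trace)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fit_descent_feasibility_and_prior_support(seed):
    spec = ip.SimulationSpec(N=35, K=5, G1=80, G2=10, h1_density=0.35,
                             missing_rate2=0.1, seed=100 + seed)
    ds, prior, _ = ip.simulate(spec)
    cfg = PenaltyConfig(lambda1=0.5, lambda2=0.5, seed=seed)
    model = ip.fit(ds, prior, cfg)
    tr = model.objective_trace
    assert (np.diff(tr) <= 1e-8 * np.maximum(1.0, np.abs(tr[:-1]))).all()
    assert (np.linalg.norm(model.X, axis=0) <= 1 + 1e-12).all()
    assert (model.B1[prior.H1 == 0] == 0).all()


def test_fit_row_sparsity_monotone_in_lambda2(small_sim):
    """Growing the row penalty never resurrects zeroed pathway rows."""
    ds, prior, _ = small_sim
    lmax = ip.lambda_max(ds, prior, "l21", PenaltyConfig(seed=5))
    zero_rows = []
    for frac in (0.05, 0.2, 0.5, 0.9):
        cfg = PenaltyConfig(lambda1=0.01, lambda2=frac * lmax, seed=5)
        model = ip.fit(ds, prior, cfg)
        zero_rows.append(int((np.abs(model.B2).sum(axis=1) == 0).sum()))
    assert all(a <= b for a, b in zip(zero_rows, zero_rows[1:]))


def test_fit_special_cases_label_the_method():
    from ipadpy.model_core import method_name
    assert method_name(PenaltyConfig(lambda1=1.0)) == "iPaD"
    assert method_name(PenaltyConfig(lambda2=1.0)) == "L21-iPaD"
    assert method_name(PenaltyConfig(lambda1=1.0, lambda2=1.0)) == "L1L21-iPaD"


def test_penalized_objective_equals_plain_when_h2_zero(masked_sim, quick_cfg):
    ds, prior, truth = masked_sim
    model = FactorModel(truth.X, truth.B1, truth.B2)
    assert penalized_objective(ds, model, prior, quick_cfg) == pytest.approx(
        objective(ds, model, quick_cfg), rel=1e-12)
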