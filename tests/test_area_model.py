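"""Model structure: precision matrices, data assembly, joint density.

The joint density is checked against an independent dense-matrix oracle that
builds every prior from explicit covariance matrices (pseudo-inverses and
null-space bases) and evaluates them with scipy's multivariate normal,
rather than the sparse quadratic-form route used by the implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space
from scipy.stats import halfnorm, multivariate_normal, norm

import caresae as cs
from caresae.area_model import (
    AdjacencyGraph,
    ModelParams,
    constrained_basis,
    icar_precision,
    icar_scaling_factor,
    log_density,
    rw1_precision,
    sum_zero_basis,
)

from conftest import tiny_model_data


class TestPrecisionMatrices:
    def test_path_graph_icar_matrix(self):
        adj = AdjacencyGraph.from_edges([(0, 1), (1, 2)], areas=[0, 1, 2])
        Q = icar_precision(adj).toarray()
        assert np.array_equal(Q, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_row_sums_zero_on_lattice(self):
        Q = icar_precision(cs.make_lattice_graph(3, 4))
        assert np.allclose(np.asarray(Q.sum(axis=1)), 0.0)

    def test_2x2_lattice_rank_three(self):
        Q = icar_precision(cs.make_lattice_graph(2, 2)).toarray()
        lam = np.linalg.eigvalsh(Q)
        assert np.sum(lam > 1e-9) == 3

    def test_rw1_is_path_graph_icar(self):
        Q3 = rw1_precision(3).toarray()
        assert np.array_equal(Q3, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_rw1_rank_deficiency_one(self, n):
        lam = np.linalg.eigvalsh(rw1_precision(n).toarray())
        assert np.sum(lam > 1e-9) == n - 1

    def test_constant_vector_in_null_space(self):
        Q = rw1_precision(6)
        v = np.ones(6)
        assert v @ (Q @ v) == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_form_shift_invariant_and_positive(self):
        Q = icar_precision(cs.make_lattice_graph(3, 3))
        rng = np.random.default_rng(0)
        v = rng.normal(size=9)
        q1 = v @ (Q @ v)
        q2 = (v + 5.0) @ (Q @ (v + 5.0))
        assert q1 == pytest.approx(q2)
        assert q1 > 0  # non-constant vector

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            rw1_precision(1)
        with pytest.raises(ValueError):
            AdjacencyGraph.from_edges([(0, 0)], areas=[0])


class TestBuildModelData:
    def test_prediction_grid_covers_every_area_year(self):
        data = tiny_model_data()
        grid = data.grid_frame()
        assert len(grid) == 3 * 2
        assert data.n_cells == 11  # one of 12 survey cells unusable

    def test_covariates_standardised(self):
        data = tiny_model_data()
        assert data.X.shape == (6, 1)
        assert data.X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        assert data.X[:, 0].std() == pytest.approx(1.0)

    def test_constant_covariate_dropped_with_warning(self):
        from conftest import tiny_direct_frame

        direct = tiny_direct_frame()
        adj = AdjacencyGraph.from_edges([(0, 1), (1, 2)], areas=[0, 1, 2])
        cov = pd.DataFrame({
            "area_id": np.repeat([0, 1, 2], 2), "year": [2015, 2016] * 3,
            "flat": 1.0,
        })
        with pytest.warns(UserWarning, match="zero-variance"):
            data = cs.build_model_data(direct, cov, adj, metric="readiness")
        assert data.X.shape[1] == 0

    def test_missing_covariate_cell_is_error(self):
        from conftest import tiny_direct_frame

        direct = tiny_direct_frame()
        adj = AdjacencyGraph.from_edges([(0, 1), (1, 2)], areas=[0, 1, 2])
        cov = pd.DataFrame({
            "area_id": [0, 0, 1, 1, 2], "year": [2015, 2016] * 2 + [2015],
            "x1": np.arange(5.0),
        })
        with pytest.raises(ValueError, match="covariate missing"):
            cs.build_model_data(direct, cov, adj, metric="readiness")


# --- dense density oracle ---------------------------------------------------


def _dense_log_density(spec, data, p: ModelParams) -> float:
    """Brute-force joint density via explicit covariance matrices."""
    pr = spec.priors
    A, T, S = data.n_areas, data.n_years, data.n_surveys
    lp = norm.logpdf(p.alpha, scale=pr.fixed_effect_sd)

    xb = np.zeros(A * T)
    if spec.use_covariates:
        lp += norm.logpdf(np.asarray(p.beta), scale=pr.fixed_effect_sd).sum()
        xb = data.X @ np.asarray(p.beta)

    comp = data.adjacency.component_labels
    if spec.spatial == "iid":
        lp += multivariate_normal.logpdf(
            p.area_iid, mean=np.zeros(A), cov=p.sigma_area**2 * np.eye(A)
        )
        lp += halfnorm.logpdf(p.sigma_area, scale=pr.sd_area)
        b = np.asarray(p.area_iid)
    else:
        sig2 = p.sigma_spatial_total**2
        lp += multivariate_normal.logpdf(
            p.area_iid, mean=np.zeros(A), cov=(1 - p.rho) * sig2 * np.eye(A)
        )
        Q = icar_precision(data.adjacency).toarray()
        c = np.exp(np.mean(np.log(np.diag(np.linalg.pinv(Q)))))
        cov_v = np.linalg.pinv(Q * c) * p.rho * sig2
        C = np.stack([(comp == k).astype(float) for k in range(comp.max() + 1)])
        basis = null_space(C)
        w = basis.T @ p.area_spatial
        lp += multivariate_normal.logpdf(
            w, mean=np.zeros(len(w)), cov=basis.T @ cov_v @ basis
        )
        lp += halfnorm.logpdf(p.sigma_spatial_total, scale=pr.sd_spatial_total)
        b = np.asarray(p.area_iid) + np.asarray(p.area_spatial)

    lp += multivariate_normal.logpdf(
        p.year_iid, mean=np.zeros(T), cov=p.sigma_year_iid**2 * np.eye(T)
    )
    Qt = rw1_precision(T).toarray()
    basis_t = null_space(np.ones((1, T)))
    cov_g = basis_t.T @ (np.linalg.pinv(Qt) * p.sigma_rw1**2) @ basis_t
    lp += multivariate_normal.logpdf(
        basis_t.T @ p.year_rw1, mean=np.zeros(T - 1), cov=cov_g
    )
    lp += halfnorm.logpdf(p.sigma_year_iid, scale=pr.sd_year_iid)
    lp += halfnorm.logpdf(p.sigma_rw1, scale=pr.sd_rw1)

    delta_cells = 0.0
    if spec.use_survey_effects:
        basis_s = null_space(np.ones((1, S)))
        w = basis_s.T @ p.survey
        lp += multivariate_normal.logpdf(
            w, mean=np.zeros(S - 1), cov=p.sigma_survey**2 * np.eye(S - 1)
        )
        lp += halfnorm.logpdf(p.sigma_survey, scale=pr.sd_survey)
        delta_cells = np.asarray(p.survey)[data.survey_idx]

    theta = (p.alpha + xb).reshape(A, T)
    theta = theta + b[:, None] + np.asarray(p.year_iid)[None, :]
    theta = theta + np.asarray(p.year_rw1)[None, :]
    mu = theta.reshape(-1)[data.grid_rows] + delta_cells
    lp += multivariate_normal.logpdf(data.y, mean=mu, cov=np.diag(data.var))
    return float(lp)


def _random_params(spec, data, rng) -> ModelParams:
    A, T, S = data.n_areas, data.n_years, data.n_surveys
    comp = data.adjacency.component_labels
    kw = dict(
        alpha=float(rng.normal()),
        area_iid=rng.normal(size=A),
        year_iid=rng.normal(size=T),
        sigma_year_iid=float(rng.uniform(0.2, 1.5)),
        sigma_rw1=float(rng.uniform(0.2, 1.5)),
    )
    gam = rng.normal(size=T)
    kw["year_rw1"] = gam - gam.mean()
    if spec.use_covariates:
        kw["beta"] = rng.normal(size=data.X.shape[1])
    if spec.spatial == "bym":
        v = rng.normal(size=A)
        for k in range(comp.max() + 1):
            v[comp == k] -= v[comp == k].mean()
        kw.update(
            area_spatial=v,
            sigma_spatial_total=float(rng.uniform(0.2, 1.5)),
            rho=float(rng.uniform(0.15, 0.85)),
        )
    else:
        kw["sigma_area"] = float(rng.uniform(0.2, 1.5))
    if spec.use_survey_effects:
        d = rng.normal(size=S)
        kw["survey"] = d - d.mean()
        kw["sigma_survey"] = float(rng.uniform(0.2, 1.5))
    return ModelParams(**kw)


@pytest.mark.parametrize("model_id", range(1, 8))
def test_log_density_matches_dense_oracle(model_id):
    """20 random parameter points per model on the 3-area x 2-year fixture."""
    data = tiny_model_data()
    spec = cs.ModelSpec.from_id(model_id)
    rng = np.random.default_rng(100 + model_id)
    for _ in range(20):
        params = _random_params(spec, data, rng)
        ours = log_density(spec, data, params)
        oracle = _dense_log_density(spec, data, params)
        assert ours == pytest.approx(oracle, abs=1e-8)


def test_data_term_is_standard_normal_at_origin():
    """With all effects zero, shifting one y from 0 to 1 changes the density
    by exactly log N(0|0,1) - log N(1|0,1) when var_logit = 1."""
    data = tiny_model_data(use_x=False)
    data.y = np.zeros(data.n_cells)
    data.var = np.ones(data.n_cells)
    spec = cs.ModelSpec.from_id(1)
    params = ModelParams(
        alpha=0.0, area_iid=np.zeros(3), year_iid=np.zeros(2),
        year_rw1=np.zeros(2), sigma_area=0.5,
    )
    base = log_density(spec, data, params)
    data.y[0] = 1.0
    shifted = log_density(spec, data, params)
    assert base - shifted == pytest.approx(norm.logpdf(0) - norm.logpdf(1))


def test_alpha_survey_tradeoff_breaks_sum_to_zero():
    """Moving mass between the intercept and the survey effects violates the
    sum-to-zero constraint, so the density changes (identifiability)."""
    data = tiny_model_data(use_x=False)
    spec = cs.ModelSpec.from_id(2)
    rng = np.random.default_rng(0)
    params = _random_params(spec, data, rng)
    base = log_density(spec, data, params)
    c = 0.3
    shifted = ModelParams(**{**params.__dict__,
                             "alpha": params.alpha + c,
                             "survey": params.survey - c})
    assert np.isfinite(base)
    assert log_density(spec, data, shifted) == -np.inf


def test_iid_models_nest_in_bym_at_zero_spatial_field():
    """M5 with a null spatial field reproduces M1's data term (and M2/M6
    reduce the same way with zero survey effects): density differences across
    two data vectors coincide."""
    data_a = tiny_model_data(use_x=False)
    data_b = tiny_model_data(use_x=False)
    data_b.y = data_b.y + 0.37
    rng = np.random.default_rng(5)
    m1 = cs.ModelSpec.from_id(1)
    p1 = _random_params(m1, data_a, rng)
    m5 = cs.ModelSpec.from_id(5)
    p5 = ModelParams(**{**p1.__dict__,
                        "sigma_area": None,
                        "area_spatial": np.zeros(3),
                        "sigma_spatial_total": 0.8, "rho": 0.5})
    diff1 = log_density(m1, data_a, p1) - log_density(m1, data_b, p1)
    diff5 = log_density(m5, data_a, p5) - log_density(m5, data_b, p5)
    assert diff1 == pytest.approx(diff5, abs=1e-10)

    m2 = cs.ModelSpec.from_id(2)
    p2 = ModelParams(**{**p1.__dict__,
                        "survey": np.zeros(data_a.n_surveys), "sigma_survey": 0.7})
    diff2 = log_density(m2, data_a, p2) - log_density(m2, data_b, p2)
    assert diff2 == pytest.approx(diff1, abs=1e-10)


def test_scaled_icar_marginal_variances_centre_on_one():
    Q = icar_precision(cs.make_lattice_graph(4, 4))
    c = icar_scaling_factor(Q)
    basis, _, _ = constrained_basis(Q)
    margvar = (basis**2).sum(axis=1) / c
    assert np.exp(np.mean(np.log(margvar))) == pytest.approx(1.0)


def test_sum_zero_basis_is_orthonormal_projection():
    H = sum_zero_basis(5)
    assert np.allclose(H.T @ H, np.eye(4))
    assert np.allclose(H.T @ np.ones(5), 0.0)
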