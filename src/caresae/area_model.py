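"""Area-level space-time smoothing models on the logit scale.

The seven model structures treat the design-weighted direct estimates
``y_logit`` as Gaussian observations of a latent area-year surface with known
sampling variances (the classic area-level / Fay-Herriot setup):

    y_{a,t,s} ~ Normal(theta_{a,t} + delta_s, var_logit_{a,t,s})
    theta_{a,t} = alpha + x_{a,t}' beta + b_a + phi_t + gamma_t

where ``b_a`` is an unstructured (IID) or BYM2 convolution (IID + scaled ICAR)
area effect, ``phi_t`` an IID year effect, ``gamma_t`` a first-order
random-walk (RW1) year effect, and ``delta_s`` an optional survey-instrument
effect absorbing systematic differences between survey tools.  ICAR, RW1 and
survey effects are constrained to sum to zero (per connected component for the
ICAR) so that ``alpha`` and ``theta`` are identified as the cross-instrument
consensus level.

Model structures (spatial flavour x covariates x survey effects):

    M1 (iid,  -,   -)      M5 (bym,  -,   -)
    M2 (iid,  -,   survey) M6 (bym,  -,   survey)
    M3 (iid,  cov, -)      M7 (bym,  cov, survey)
    M4 (iid,  cov, survey)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import helmert
from scipy.stats import norm

__all__ = [
    "AdjacencyGraph",
    "PriorConfig",
    "ModelSpec",
    "ModelData",
    "ModelParams",
    "icar_precision",
    "rw1_precision",
    "constrained_basis",
    "icar_scaling_factor",
    "sum_zero_basis",
    "build_model_data",
    "log_density",
]

_SUM_ZERO_TOL = 1e-8


class AdjacencyGraph:
    """Undirected areal adjacency with a fixed area ordering.

    Wraps a :class:`networkx.Graph`; validates symmetry-by-construction
    properties (no self-loops) and labels connected components, which each
    receive their own sum-to-zero constraint in the ICAR prior.
    """

    def __init__(self, graph: nx.Graph, areas=None):
        if graph.number_of_nodes() == 0:
            raise ValueError("adjacency graph has no areas")
        for u, v in graph.edges():
            if u == v:
                raise ValueError(f"self-loop on area {u!r}")
        if areas is None:
            areas = sorted(graph.nodes, key=str)
        else:
            areas = list(areas)
            missing = set(areas) - set(graph.nodes)
            extra = set(graph.nodes) - set(areas)
            if missing or extra:
                raise ValueError(
                    f"area list does not match graph nodes (missing={missing}, extra={extra})"
                )
        self.graph = graph
        self.areas = areas
        self._index = {a: i for i, a in enumerate(areas)}
        labels = np.empty(len(areas), dtype=int)
        for k, comp in enumerate(nx.connected_components(graph)):
            for a in comp:
                labels[self._index[a]] = k
        self.component_labels = labels
        self.n_components = int(labels.max()) + 1

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def index(self, area) -> int:
        return self._index[area]

    @classmethod
    def from_edges(cls, edges, areas=None) -> "AdjacencyGraph":
        g = nx.Graph()
        if areas is not None:
            g.add_nodes_from(areas)
        g.add_edges_from(edges)
        return cls(g, areas=areas)


def icar_precision(adjacency) -> sp.csr_matrix:
    """ICAR structure matrix Q: degree on the diagonal, -1 for neighbours.

    This is exactly the graph Laplacian; row sums are zero and the rank
    deficiency equals the number of connected components.
    """
    if isinstance(adjacency, AdjacencyGraph):
        graph, nodelist = adjacency.graph, adjacency.areas
    else:
        graph, nodelist = adjacency, sorted(adjacency.nodes, key=str)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return sp.csr_matrix(nx.laplacian_matrix(graph, nodelist=nodelist), dtype=float)


def rw1_precision(n_years: int) -> sp.csr_matrix:
    """First-order random-walk structure matrix (path-graph ICAR on years)."""
    if n_years < 2:
        raise ValueError("RW1 needs at least 2 years")
    return icar_precision(AdjacencyGraph(nx.path_graph(n_years), areas=range(n_years)))


def constrained_basis(Q, tol: float = 1e-9):
    """Spectral basis of an intrinsic GMRF restricted to its non-null space.

    Returns ``(A, logpdet, rank)`` where columns of ``A`` are eigenvectors of
    ``Q`` scaled by 1/sqrt(eigenvalue).  If ``w ~ N(0, I_rank)`` then
    ``A @ w`` has the intrinsic density with structure ``Q`` and unit
    variance parameter, supported on the subspace orthogonal to the null
    space (i.e. sum-to-zero per connected component for ICAR/RW1).
    """
    Qd = np.asarray(Q.todense() if sp.issparse(Q) else Q, dtype=float)
    lam, V = np.linalg.eigh(Qd)
    keep = lam > tol * max(lam.max(), 1.0)
    basis = V[:, keep] / np.sqrt(lam[keep])
    return basis, float(np.log(lam[keep]).sum()), int(keep.sum())


def icar_scaling_factor(Q) -> float:
    """BYM2 scaling: geometric mean of the marginal variances of the ICAR.

    Dividing the ICAR effect by sqrt of this factor gives a spatial field
    whose typical marginal variance is 1, so the BYM2 total standard
    deviation is interpretable across graphs.
    """
    basis, _, _ = constrained_basis(Q)
    margvar = (basis**2).sum(axis=1)
    return float(np.exp(np.mean(np.log(margvar))))


def sum_zero_basis(n: int) -> np.ndarray:
    """Orthonormal basis (n x n-1) of the sum-to-zero subspace of R^n."""
    if n < 2:
        raise ValueError("need n >= 2 for a sum-to-zero effect")
    return helmert(n).T


@dataclass(frozen=True)
class PriorConfig:
    """Prior scales. Half-normal(0, scale) on every random-effect sd,
    Normal(0, fixed_effect_sd^2) on intercept and slopes, Uniform(0,1) on the
    BYM2 mixing fraction."""

    sd_area: float = 1.0          # iid area sd (models 1-4)
    sd_spatial_total: float = 1.0  # BYM2 total area sd (models 5-7)
    sd_year_iid: float = 1.0
    sd_rw1: float = 1.0
    sd_survey: float = 1.0
    fixed_effect_sd: float = 5.0

    def __post_init__(self):
        for f in (
            "sd_area", "sd_spatial_total", "sd_year_iid",
            "sd_rw1", "sd_survey", "fixed_effect_sd",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"prior scale {f} must be > 0")


_MODEL_TABLE = {
    1: ("iid", False, False),
    2: ("iid", False, True),
    3: ("iid", True, False),
    4: ("iid", True, True),
    5: ("bym", False, False),
    6: ("bym", False, True),
    7: ("bym", True, True),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the seven model structures plus priors."""

    model_id: int
    spatial: str  # 'iid' or 'bym'
    use_covariates: bool
    use_survey_effects: bool
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if self.spatial not in ("iid", "bym"):
            raise ValueError("spatial must be 'iid' or 'bym'")
        if self.model_id in _MODEL_TABLE:
            expected = _MODEL_TABLE[self.model_id]
            got = (self.spatial, self.use_covariates, self.use_survey_effects)
            if expected != got:
                raise ValueError(
                    f"model {self.model_id} is fixed as {expected}, got {got}"
                )

    @classmethod
    def from_id(cls, model_id: int, priors: PriorConfig | None = None) -> "ModelSpec":
        if model_id not in _MODEL_TABLE:
            raise ValueError(f"model_id must be in 1..7, got {model_id}")
        spatial, cov, surv = _MODEL_TABLE[model_id]
        return cls(model_id, spatial, cov, surv, priors or PriorConfig())


@dataclass
class ModelData:
    """Stacked usable direct estimates plus the full prediction grid.

    The grid is row-major over (area, year): grid row = area_idx * n_years +
    year_idx.  ``X`` holds standardized covariates over the full grid (may
    have zero columns).  ``cells`` retains every input cell, usable or not,
    for reporting.
    """

    metric: str
    y: np.ndarray
    var: np.ndarray
    area_idx: np.ndarray
    year_idx: np.ndarray
    survey_idx: np.ndarray
    areas: list
    years: list
    surveys: list
    X: np.ndarray
    covariate_names: list
    adjacency: AdjacencyGraph
    cells: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.y)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_surveys(self) -> int:
        return len(self.surveys)

    @property
    def grid_rows(self) -> np.ndarray:
        """Grid row of each likelihood cell."""
        return self.area_idx * self.n_years + self.year_idx

    def grid_frame(self) -> pd.DataFrame:
        areas = np.repeat(self.areas, self.n_years)
        years = np.tile(self.years, self.n_areas)
        return pd.DataFrame({"area_id": areas, "year": years})

    def drop_cells(self, mask: np.ndarray) -> "ModelData":
        """New ModelData without the masked likelihood cells.

        The prediction grid, covariates, area/year/survey index sets are kept
        unchanged, so hold-out refits predict the same grid.
        """
        keep = ~np.asarray(mask, dtype=bool)
        if keep.sum() == 0:
            raise ValueError("cannot drop every usable cell")
        return replace(
            self,
            y=self.y[keep],
            var=self.var[keep],
            area_idx=self.area_idx[keep],
            year_idx=self.year_idx[keep],
            survey_idx=self.survey_idx[keep],
        )


def build_model_data(
    direct: pd.DataFrame,
    covariates: pd.DataFrame | None,
    adjacency: AdjacencyGraph,
    metric: str | None = None,
    years=None,
    surveys=None,
) -> ModelData:
    """Assemble the likelihood stack and prediction grid for one metric.

    Parameters
    ----------
    direct
        Direct-estimate table (one row per area-year-survey cell) with at
        least area_id, year, survey_id, metric, y_logit, var_logit, usable.
    covariates
        Long table (area_id, year, one column per covariate) covering every
        area-year of the prediction grid, or None for covariate-free models.
        Columns are centered and scaled to unit variance over the grid;
        zero-variance columns are dropped with a warning.
    years
        Prediction years (contiguous).  Defaults to the span of the data;
        pass a longer range to extrapolate through the RW1.
    """
    df = direct
    if metric is not None:
        df = df[df["metric"] == metric]
    metrics_present = df["metric"].unique()
    if len(metrics_present) != 1:
        raise ValueError(f"expected exactly one metric, got {list(metrics_present)}")
    metric = metrics_present[0]

    usable = df[df["usable"].astype(bool)].copy()
    if len(usable) == 0:
        raise ValueError("no usable cells")

    if years is None:
        years = list(range(int(df["year"].min()), int(df["year"].max()) + 1))
    else:
        years = [int(t) for t in years]
        if years != list(range(years[0], years[-1] + 1)):
            raise ValueError("years must be contiguous")
    if surveys is None:
        surveys = sorted(usable["survey_id"].unique(), key=str)
    else:
        surveys = list(surveys)

    areas = adjacency.areas
    unknown = set(usable["area_id"]) - set(areas)
    if unknown:
        raise ValueError(f"usable cells reference areas not in the graph: {unknown}")
    bad_years = set(usable["year"].astype(int)) - set(years)
    if bad_years:
        raise ValueError(f"usable cells outside the year range: {bad_years}")

    area_idx = usable["area_id"].map(adjacency.index).to_numpy(dtype=int)
    year_idx = usable["year"].astype(int).map({t: i for i, t in enumerate(years)})
    year_idx = year_idx.to_numpy(dtype=int)
    survey_map = {s: i for i, s in enumerate(surveys)}
    if set(usable["survey_id"]) - set(surveys):
        raise ValueError("usable cells reference surveys not in the survey list")
    survey_idx = usable["survey_id"].map(survey_map).to_numpy(dtype=int)

    n_grid = len(areas) * len(years)
    if covariates is None:
        X = np.zeros((n_grid, 0))
        names: list = []
    else:
        cov = covariates.set_index(["area_id", "year"])
        grid_index = pd.MultiIndex.from_product([areas, years], names=["area_id", "year"])
        try:
            cov = cov.loc[grid_index]
        except KeyError as exc:
            raise ValueError(f"covariate missing for a predicted area-year: {exc}") from exc
        names = [c for c in cov.columns]
        X = cov.to_numpy(dtype=float)
        sd = X.std(axis=0)
        const = sd <= 0
        if const.any():
            dropped = [n for n, c in zip(names, const) if c]
            warnings.warn(f"dropping zero-variance covariates: {dropped}")
            X = X[:, ~const]
            names = [n for n, c in zip(names, const) if not c]
            sd = sd[~const]
        if X.shape[1]:
            X = (X - X.mean(axis=0)) / sd

    return ModelData(
        metric=metric,
        y=usable["y_logit"].to_numpy(dtype=float),
        var=usable["var_logit"].to_numpy(dtype=float),
        area_idx=area_idx,
        year_idx=year_idx,
        survey_idx=survey_idx,
        areas=list(areas),
        years=years,
        surveys=surveys,
        X=X,
        covariate_names=names,
        adjacency=adjacency,
        cells=df.copy(),
    )


@dataclass
class ModelParams:
    """Explicit latent effects and variance parameters for density evaluation.

    Constrained blocks (area_spatial, year_rw1, survey) must satisfy their
    sum-to-zero constraints; the density is -inf otherwise, which is what
    enforces identifiability of alpha against the survey offsets.
    """

    alpha: float
    beta: np.ndarray | None = None
    area_iid: np.ndarray | None = None
    area_spatial: np.ndarray | None = None
    year_iid: np.ndarray | None = None
    year_rw1: np.ndarray | None = None
    survey: np.ndarray | None = None
    sigma_area: float | None = None           # iid area sd (models 1-4)
    sigma_spatial_total: float | None = None  # BYM2 total sd (models 5-7)
    rho: float | None = None                  # BYM2 mixing fraction
    sigma_year_iid: float = 1.0
    sigma_rw1: float = 1.0
    sigma_survey: float | None = None


def _half_normal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(norm.logpdf(x, scale=scale) + np.log(2.0))


def _intrinsic_logpdf(x: np.ndarray, Q, logpdet: float, rank: int, variance: float) -> float:
    quad = float(x @ (Q @ x))
    return -0.5 * rank * np.log(2 * np.pi * variance) + 0.5 * logpdet - quad / (2 * variance)


def log_density(spec: ModelSpec, data: ModelData, params: ModelParams) -> float:
    """Log joint density: Gaussian likelihood x effect priors x hyperpriors.

    Evaluates log of

        prod_cells N(y | theta_{a,t} + delta_s, var_logit)
        x N(alpha) N(beta) N(area_iid) ICAR(area_spatial) N(year_iid)
          RW1(year_rw1) N(survey | sum-to-zero)
        x half-normal(sd's) x Uniform(rho)

    with theta as in the module docstring.  Intrinsic priors (ICAR, RW1) are
    evaluated on their constrained subspace with pseudo-determinant
    normalisation; the sum-to-zero survey prior likewise.  Violating a
    constraint returns -inf.
    """
    pr = spec.priors
    A, T, S = data.n_areas, data.n_years, data.n_surveys
    alpha = float(params.alpha)
    if not np.isfinite(alpha):
        raise ValueError("non-finite alpha")

    logp = float(norm.logpdf(alpha, scale=pr.fixed_effect_sd))

    # --- fixed effects
    if spec.use_covariates:
        beta = np.asarray(params.beta, dtype=float)
        if beta.shape != (data.X.shape[1],):
            raise ValueError("beta has wrong length")
        logp += float(norm.logpdf(beta, scale=pr.fixed_effect_sd).sum())
        xb = data.X @ beta
    else:
        if params.beta is not None and len(np.atleast_1d(params.beta)):
            raise ValueError("beta supplied but spec has no covariates")
        xb = np.zeros(A * T)

    # --- area effects
    u = np.asarray(params.area_iid, dtype=float)
    if u.shape != (A,):
        raise ValueError("area_iid has wrong length")
    if spec.spatial == "iid":
        if params.area_spatial is not None:
            raise ValueError("area_spatial supplied for an iid-spatial spec")
        sigma_u = float(params.sigma_area)
        if sigma_u <= 0:
            return -np.inf
        logp += float(norm.logpdf(u, scale=sigma_u).sum())
        logp += _half_normal_logpdf(sigma_u, pr.sd_area)
        b = u
    else:
        v = np.asarray(params.area_spatial, dtype=float)
        if v.shape != (A,):
            raise ValueError("area_spatial has wrong length")
        sigma_b = float(params.sigma_spatial_total)
        rho = float(params.rho)
        if sigma_b <= 0 or not (0.0 < rho < 1.0):
            return -np.inf
        comp = data.adjacency.component_labels
        for k in range(data.adjacency.n_components):
            if abs(v[comp == k].sum()) > _SUM_ZERO_TOL:
                return -np.inf
        Q = icar_precision(data.adjacency)
        scale_c = icar_scaling_factor(Q)
        Qs = Q * scale_c
        _, logpdet_q, rank_q = constrained_basis(Q)
        logpdet_s = logpdet_q + rank_q * np.log(scale_c)
        logp += float(norm.logpdf(u, scale=sigma_b * np.sqrt(1 - rho)).sum())
        logp += _intrinsic_logpdf(v, Qs, logpdet_s, rank_q, rho * sigma_b**2)
        logp += _half_normal_logpdf(sigma_b, pr.sd_spatial_total)
        b = u + v

    # --- year effects
    phi = np.asarray(params.year_iid, dtype=float)
    gam = np.asarray(params.year_rw1, dtype=float)
    if phi.shape != (T,) or gam.shape != (T,):
        raise ValueError("year effects have wrong length")
    if abs(gam.sum()) > _SUM_ZERO_TOL:
        return -np.inf
    s_phi, s_gam = float(params.sigma_year_iid), float(params.sigma_rw1)
    if s_phi <= 0 or s_gam <= 0:
        return -np.inf
    logp += float(norm.logpdf(phi, scale=s_phi).sum())
    Qt = rw1_precision(T)
    _, logpdet_t, rank_t = constrained_basis(Qt)
    logp += _intrinsic_logpdf(gam, Qt, logpdet_t, rank_t, s_gam**2)
    logp += _half_normal_logpdf(s_phi, pr.sd_year_iid)
    logp += _half_normal_logpdf(s_gam, pr.sd_rw1)

    # --- survey effects
    if spec.use_survey_effects:
        delta = np.asarray(params.survey, dtype=float)
        if delta.shape != (S,):
            raise ValueError("survey effects have wrong length")
        if abs(delta.sum()) > _SUM_ZERO_TOL:
            return -np.inf
        s_del = float(params.sigma_survey)
        if s_del <= 0:
            return -np.inf
        # N(0, sigma^2 (I - J/S)) restricted to the sum-to-zero subspace
        logp += -0.5 * (S - 1) * np.log(2 * np.pi * s_del**2) - float(
            delta @ delta
        ) / (2 * s_del**2)
        logp += _half_normal_logpdf(s_del, pr.sd_survey)
        delta_cells = delta[data.survey_idx]
    else:
        if params.survey is not None:
            raise ValueError("survey effects supplied but spec has none")
        delta_cells = 0.0

    # --- likelihood
    theta = (alpha + xb).reshape(A, T) + b[:, None] + phi[None, :] + gam[None, :]
    mu = theta.reshape(-1)[data.grid_rows] + delta_cells
    if not np.all(np.isfinite(data.y)) or not np.all(np.isfinite(mu)):
        raise ValueError("non-finite likelihood inputs")
    logp += float(norm.logpdf(data.y, loc=mu, scale=np.sqrt(data.var)).sum())
    return logp
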