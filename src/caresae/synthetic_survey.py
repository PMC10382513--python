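"""Synthetic multi-instrument facility surveys with known ground truth.

Emulates the structure of standardized health-facility assessments (SPA/SDI
style): a sampling frame stratified by facility type x managing authority x
area, several overlapping survey instruments with systematic logit-scale
offsets, and binary item/protocol indicators driven by latent area-year
quality surfaces with spatial (neighbour-correlated), temporal (smooth
trend) and covariate structure.  Because the truth is known, estimator
unbiasedness, parameter recovery and interval calibration are all testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .area_model import (
    AdjacencyGraph,
    constrained_basis,
    icar_precision,
    icar_scaling_factor,
    rw1_precision,
)
from .util import substream

__all__ = [
    "StratumSpec",
    "SurveyWave",
    "SimConfig",
    "SimTruth",
    "make_lattice_graph",
    "make_covariates",
    "build_frame",
    "simulate_truth",
    "draw_survey",
    "simulate_dataset",
]


@dataclass(frozen=True)
class StratumSpec:
    """One design stratum: facility type x managing authority, with the
    number of frame facilities per area."""

    facility_type: str
    managing_authority: str
    frame_per_area: int

    @property
    def key(self) -> str:
        return f"{self.facility_type}/{self.managing_authority}"


@dataclass(frozen=True)
class SurveyWave:
    """One survey instrument wave: which year it measures, the sampling
    fraction per stratum, and its systematic instrument offset (logit)."""

    survey_id: str
    year: int
    fractions: dict  # stratum key -> sampling fraction in (0, 1]
    offset: float = 0.0

    def __post_init__(self):
        for k, f in self.fractions.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"sampling fraction for {k} must be in (0,1], got {f}")


def _default_strata() -> tuple:
    return (
        StratumSpec("hospital", "public", 2),
        StratumSpec("health_center", "public", 6),
        StratumSpec("clinic", "private", 4),
    )


def _default_surveys() -> tuple:
    # two instrument families with opposite systematic offsets, four waves
    # spanning the study period; hospitals are taken as a census, lower-level
    # facilities sampled at unequal fractions (typical of SPA-type designs).
    # The two instruments overlap in 2017 (as SPA and SDI did in real survey
    # series), which is what identifies the instrument offsets against the
    # year effects.
    fr_a = {"hospital/public": 1.0, "health_center/public": 0.5, "clinic/private": 0.35}
    fr_b = {"hospital/public": 1.0, "health_center/public": 0.6, "clinic/private": 0.25}
    return (
        SurveyWave("spa_2013", 2013, fr_a, +0.25),
        SurveyWave("sdi_2015", 2015, fr_b, -0.25),
        SurveyWave("spa_2017", 2017, fr_a, +0.25),
        SurveyWave("sdi_2017", 2017, fr_b, -0.25),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults give a 4x4 area lattice observed over 8 years by two instrument
    families (offsets +/-0.25 logits), with moderate spatial and temporal
    structure and two predictive covariates.
    """

    n_rows: int = 4
    n_cols: int = 4
    years: tuple = tuple(range(2012, 2020))
    n_items: int = 12
    n_protocols: int = 15
    strata: tuple = field(default_factory=_default_strata)
    surveys: tuple = field(default_factory=_default_surveys)
    intercept_readiness: float = logit(0.55)
    intercept_process: float = logit(0.40)
    beta_readiness: tuple = (0.30, -0.20)
    beta_process: tuple = (0.25, -0.15)
    sigma_spatial: float = 0.5    # scaled-ICAR marginal sd
    sigma_area_iid: float = 0.20
    sigma_rw1: float = 0.15       # innovation-scale sd of the year walk
    sigma_year_iid: float = 0.10
    facility_sd: float = 0.30     # facility-level IID logit perturbation
    consultation_mean: float = 3.0  # Poisson mean, truncated at >= 1
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        ys = list(self.years)
        if ys != list(range(ys[0], ys[-1] + 1)):
            raise ValueError("years must be contiguous")
        if self.n_protocols < 1:
            raise ValueError("n_protocols must be >= 1")
        for s in (self.sigma_spatial, self.sigma_area_iid, self.sigma_rw1,
                  self.sigma_year_iid, self.facility_sd):
            if s < 0:
                raise ValueError("variances must be >= 0")
        for wave in self.surveys:
            if wave.year not in self.years:
                raise ValueError(f"survey {wave.survey_id} year {wave.year} outside range")

    @property
    def n_areas(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class SimTruth:
    """Latent quality surfaces and effects the models target."""

    areas: list
    years: list
    theta_readiness: np.ndarray  # (A, T) true means in (0,1)
    theta_process: np.ndarray
    area_effects: dict           # metric -> (A,) total area effect
    year_effects: dict           # metric -> (T,) total year effect
    survey_offsets: dict         # survey_id -> logit offset
    betas: dict                  # metric -> coefficient vector

    def theta(self, metric: str) -> np.ndarray:
        return self.theta_readiness if metric == "readiness" else self.theta_process

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in ("readiness", "process_quality"):
            th = self.theta(metric)
            for i, a in enumerate(self.areas):
                for j, t in enumerate(self.years):
                    rows.append({"metric": metric, "area_id": a, "year": t,
                                 "theta": th[i, j]})
        return pd.DataFrame(rows)


def make_lattice_graph(n_rows: int, n_cols: int) -> AdjacencyGraph:
    """Rook-adjacency lattice on n_rows x n_cols areas, nodes 0..N-1."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    g2 = nx.grid_2d_graph(n_rows, n_cols)
    mapping = {(r, c): r * n_cols + c for r, c in g2.nodes}
    g = nx.relabel_nodes(g2, mapping)
    return AdjacencyGraph(g, areas=range(n_rows * n_cols))


def make_covariates(graph: AdjacencyGraph, years, n_cov: int = 2, rng=None) -> pd.DataFrame:
    """Area-year covariates with spatial and temporal autocorrelation.

    Each covariate is a spatially smooth area field (scaled-ICAR draw when the
    graph admits one, else IID) plus a linear time trend and white noise —
    a rough stand-in for remotely sensed predictors such as accessibility or
    night-time lights.
    """
    rng = rng or np.random.default_rng(0)
    A, T = graph.n_areas, len(list(years))
    Q = icar_precision(graph)
    basis, _, rank = constrained_basis(Q)
    if rank:
        basis = basis / np.sqrt(icar_scaling_factor(Q))
    rows = []
    for k in range(n_cov):
        spatial = basis @ rng.normal(size=rank) if rank else rng.normal(size=A)
        trend = rng.normal(scale=0.5) * np.linspace(-1, 1, T)
        x = spatial[:, None] + trend[None, :] + rng.normal(scale=0.3, size=(A, T))
        rows.append(x.reshape(-1))
    years = list(years)
    out = pd.DataFrame({
        "area_id": np.repeat(graph.areas, T),
        "year": np.tile(years, A),
    })
    for k, x in enumerate(rows):
        out[f"x{k + 1}"] = x
    return out


def build_frame(config: SimConfig) -> pd.DataFrame:
    """Sampling frame: every facility in every area and stratum."""
    rows = []
    fid = 0
    for area in range(config.n_areas):
        for st in config.strata:
            for _ in range(st.frame_per_area):
                rows.append({
                    "facility_id": f"f{fid:05d}",
                    "area_id": area,
                    "stratum": f"{st.key}/area{area}",
                    "facility_type": st.facility_type,
                    "managing_authority": st.managing_authority,
                    "stratum_key": st.key,
                })
                fid += 1
    return pd.DataFrame(rows)


def _structured_effects(config: SimConfig, graph: AdjacencyGraph, rng):
    """Draw one latent surface's effects: spatial + iid area, RW1 + iid year."""
    A, T = config.n_areas, len(config.years)
    Q = icar_precision(graph)
    basis, _, rank = constrained_basis(Q)
    spatial = np.zeros(A)
    if rank and config.sigma_spatial > 0:
        scaled = basis / np.sqrt(icar_scaling_factor(Q))
        spatial = config.sigma_spatial * (scaled @ rng.normal(size=rank))
    area = spatial + config.sigma_area_iid * rng.normal(size=A)
    year = config.sigma_year_iid * rng.normal(size=T)
    if T >= 2 and config.sigma_rw1 > 0:
        tb, _, tr = constrained_basis(rw1_precision(T))
        year = year + config.sigma_rw1 * (tb @ rng.normal(size=tr))
    return area, year


def simulate_truth(
    config: SimConfig, graph: AdjacencyGraph, covariates: pd.DataFrame
) -> SimTruth:
    """Latent area-year surfaces: logit(theta) = intercept + X beta +
    spatial + temporal + IID effects, reproducible from the config seed."""
    if graph.n_areas != config.n_areas:
        raise ValueError("graph does not match the configured lattice")
    areas = list(graph.areas)
    years = list(config.years)
    cov = covariates.set_index(["area_id", "year"])
    grid = pd.MultiIndex.from_product([areas, years], names=["area_id", "year"])
    try:
        X = cov.loc[grid].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"covariates missing for area-year {exc}") from exc
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    A, T = len(areas), len(years)

    thetas, area_eff, year_eff, betas = {}, {}, {}, {}
    for metric, intercept, beta in (
        ("readiness", config.intercept_readiness, config.beta_readiness),
        ("process_quality", config.intercept_process, config.beta_process),
    ):
        rng = substream(config.seed, "truth", metric)
        beta = np.asarray(beta, dtype=float)
        if X.shape[1] != beta.size:
            raise ValueError(
                f"{X.shape[1]} covariates but {beta.size} coefficients for {metric}"
            )
        a_eff, t_eff = _structured_effects(config, graph, rng)
        eta = intercept + (X @ beta).reshape(A, T) + a_eff[:, None] + t_eff[None, :]
        thetas[metric] = expit(eta)
        area_eff[metric], year_eff[metric], betas[metric] = a_eff, t_eff, beta

    return SimTruth(
        areas=areas,
        years=years,
        theta_readiness=thetas["readiness"],
        theta_process=thetas["process_quality"],
        area_effects=area_eff,
        year_effects=year_eff,
        survey_offsets={w.survey_id: w.offset for w in config.surveys},
        betas=betas,
    )


def draw_survey(
    frame: pd.DataFrame, truth: SimTruth, wave: SurveyWave, config: SimConfig,
    seed: int | None = None,
):
    """Sample one survey wave and generate its facility/consultation tables.

    Facilities are Bernoulli-sampled independently within each stratum at the
    wave's fraction; weight = 1/inclusion probability.  Each sampled facility
    gets ``n_items`` Bernoulli item indicators with success probability
    inverse-logit(logit theta_readiness + instrument offset + facility
    perturbation), and a truncated-Poisson number of consultations whose
    protocol indicators are drawn the same way from theta_process.
    """
    rng = substream(config.seed if seed is None else seed, "survey", wave.survey_id)
    t_idx = truth.years.index(wave.year)
    a_index = {a: i for i, a in enumerate(truth.areas)}

    missing = set(frame["stratum_key"]) - set(wave.fractions)
    if missing:
        raise ValueError(f"no sampling fraction for strata {missing}")
    for key, frac in wave.fractions.items():
        if frac > 0 and (frame["stratum_key"] == key).sum() == 0:
            raise ValueError(f"empty stratum {key} with positive sampling fraction")

    prob = frame["stratum_key"].map(wave.fractions).to_numpy(dtype=float)
    take = rng.random(len(frame)) < prob
    sampled = frame.loc[take].copy()
    sampled["weight"] = 1.0 / prob[take]
    sampled["survey_id"] = wave.survey_id
    sampled["year"] = wave.year

    n = len(sampled)
    area_i = sampled["area_id"].map(a_index).to_numpy()
    eta_read = (
        logit(truth.theta_readiness[area_i, t_idx])
        + wave.offset
        + config.facility_sd * rng.normal(size=n)
    )
    items = (rng.random((n, config.n_items)) < expit(eta_read)[:, None]).astype(int)
    fac = sampled[[
        "facility_id", "area_id", "year", "survey_id", "stratum", "weight",
        "facility_type", "managing_authority",
    ]].reset_index(drop=True)
    for j in range(config.n_items):
        fac[f"item_{j + 1}"] = items[:, j]

    eta_proc = (
        logit(truth.theta_process[area_i, t_idx])
        + wave.offset
        + config.facility_sd * rng.normal(size=n)
    )
    n_cons = np.maximum(rng.poisson(config.consultation_mean, size=n), 1)
    crows = []
    p_proc = expit(eta_proc)
    for i, (fid, k) in enumerate(zip(fac["facility_id"], n_cons)):
        draws = (rng.random((k, config.n_protocols)) < p_proc[i]).astype(int)
        for c in range(k):
            row = {"consultation_id": f"{wave.survey_id}_{fid}_c{c}", "facility_id": fid}
            row.update({f"protocol_{j + 1}": draws[c, j] for j in range(config.n_protocols)})
            crows.append(row)
    cons = pd.DataFrame(crows)
    return fac, cons


def simulate_dataset(config: SimConfig) -> dict:
    """End-to-end simulation: graph, covariates, truth, frame and all waves.

    Returns a dict with keys graph, covariates, truth, frame,
    facility_table, consultation_table.
    """
    graph = make_lattice_graph(config.n_rows, config.n_cols)
    covariates = make_covariates(
        graph, config.years,
        n_cov=len(config.beta_readiness),
        rng=substream(config.seed, "covariates"),
    )
    truth = simulate_truth(config, graph, covariates)
    frame = build_frame(config)
    fac_parts, con_parts = [], []
    for wave in config.surveys:
        f, c = draw_survey(frame, truth, wave, config)
        fac_parts.append(f)
        con_parts.append(c)
    return {
        "graph": graph,
        "covariates": covariates,
        "truth": truth,
        "frame": frame,
        "facility_table": pd.concat(fac_parts, ignore_index=True),
        "consultation_table": pd.concat(con_parts, ignore_index=True),
    }
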