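"""Hold-one-area-out cross-validation with bias/precision/calibration summaries.

For every validation cell, the model is refitted with all survey
observations of that area-year removed, and the held-out direct estimate is
scored against the refit's posterior predictive (latent surface + the
held-out instrument's survey effect + the cell's known sampling noise) at
the 50/80/95% levels.  Validation cells are those whose design-based
precision exceeds the median precision, per metric, since sparse cells'
direct estimates are too noisy to serve as a benchmark.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .area_model import ModelData, ModelSpec
from .inference import CV_SAMPLER, SamplerConfig, fit_model
from .util import substream

logger = logging.getLogger(__name__)

__all__ = [
    "CVRecord",
    "CVSummary",
    "make_validation_set",
    "holdout_predict",
    "run_holdout_cv",
    "summarize_cv",
]

_LEVELS = (0.50, 0.80, 0.95)


@dataclass(frozen=True)
class CVRecord:
    area_id: object
    year: int
    survey_id: object
    metric: str
    observed: float        # held-out direct p-hat
    predicted: float       # posterior predictive mean, probability scale
    lower50: float
    upper50: float
    lower80: float
    upper80: float
    lower95: float
    upper95: float

    def __post_init__(self):
        nested = (
            self.lower95 <= self.lower80 <= self.lower50
            and self.upper50 <= self.upper80 <= self.upper95
        )
        if not nested:
            raise ValueError("interval bounds must nest: 50% within 80% within 95%")


@dataclass(frozen=True)
class CVSummary:
    mean_error: float
    mean_abs_error: float
    coverage50: float
    coverage80: float
    coverage95: float
    n_cells: int


def make_validation_set(
    direct: pd.DataFrame, group_cols=("metric",)
) -> pd.DataFrame:
    """Usable cells whose precision (1/var_p) strictly exceeds the median.

    The median is computed within each group (per metric by default).  If
    every precision in a group ties the median, the strict rule would empty
    the group; it then falls back to >= with a warning.
    """
    usable = direct[direct["usable"].astype(bool)].copy()
    if len(usable) < 2:
        raise ValueError("need at least 2 usable cells to form a validation set")
    usable["precision"] = 1.0 / usable["var_p"]
    parts = []
    for _, grp in usable.groupby(list(group_cols), sort=True):
        med = grp["precision"].median()
        keep = grp[grp["precision"] > med]
        if keep.empty:
            warnings.warn(
                "all precisions tie the median; keeping cells with precision >= median"
            )
            keep = grp[grp["precision"] >= med]
        parts.append(keep)
    return pd.concat(parts).drop(columns="precision")


def holdout_predict(
    spec: ModelSpec,
    data: ModelData,
    target: tuple,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
) -> list[CVRecord]:
    """Refit without every survey cell of ``target`` = (area_id, year) and
    score each held-out cell against the refit's posterior predictive.

    The prediction grid is unchanged by the hold-out.  One record is
    returned per held-out survey cell, since the observed direct estimates
    are instrument-specific.
    """
    area_id, year = target
    a = data.adjacency.index(area_id)
    t = data.years.index(int(year))
    mask = (data.area_idx == a) & (data.year_idx == t)
    if mask.sum() == 0:
        raise ValueError(f"no usable cells for target {target}")
    held_y = data.y[mask]
    held_var = data.var[mask]
    held_surv = data.survey_idx[mask]
    # facilities per held-out cell, for the t degrees of freedom below
    cells = data.cells
    cell_df = {}
    for r in cells[cells["usable"].astype(bool)].itertuples():
        n_strata = int(getattr(r, "n_strata", 1))
        cell_df[(r.area_id, int(r.year), r.survey_id)] = int(r.n) - n_strata

    reduced = data.drop_cells(mask)
    draws, diag = fit_model(spec, reduced, sampler or CV_SAMPLER, seed=seed)
    if not diag.converged:
        logger.debug("hold-out refit for %s flagged: %s", target, diag.messages)

    g = a * data.n_years + t
    rng = substream(seed, "cv-predictive", str(area_id), int(year))
    records = []
    for y_obs, v_obs, s_idx in zip(held_y, held_var, held_surv):
        eta = draws.theta[:, g] + draws.survey[:, s_idx]
        # sampling noise of the held-out direct estimate: Student-t with the
        # cell's design degrees of freedom (facilities minus strata), since
        # its variance is itself estimated from few facilities
        df = max(cell_df.get((area_id, int(year), data.surveys[s_idx]), 3), 3)
        noise = rng.standard_t(df, size=draws.n_draws) * np.sqrt(v_obs)
        pred = expit(eta + noise)
        qs = {}
        for lev in _LEVELS:
            half = (1.0 - lev) / 2.0
            qs[lev] = (float(np.quantile(pred, half)), float(np.quantile(pred, 1 - half)))
        records.append(CVRecord(
            area_id=area_id, year=int(year), survey_id=data.surveys[s_idx],
            metric=data.metric,
            observed=float(expit(y_obs)),
            predicted=float(pred.mean()),
            lower50=qs[0.50][0], upper50=qs[0.50][1],
            lower80=qs[0.80][0], upper80=qs[0.80][1],
            lower95=qs[0.95][0], upper95=qs[0.95][1],
        ))
    return records


def run_holdout_cv(
    spec: ModelSpec,
    data: ModelData,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
    targets=None,
) -> list[CVRecord]:
    """Filter to the validation set, hold out each area-year, collect records.

    ``targets`` overrides the precision-median filter with an explicit list
    of (area_id, year) pairs.  Refit failures are logged and skipped.
    """
    if targets is None:
        vset = make_validation_set(data.cells[data.cells["metric"] == data.metric])
        targets = sorted(
            {(r.area_id, int(r.year)) for r in vset.itertuples()}, key=str
        )
    records: list[CVRecord] = []
    n_failed = 0
    for target in targets:
        try:
            records.extend(holdout_predict(spec, data, target, sampler, seed=seed))
        except Exception as exc:  # refit failure: skip and count
            n_failed += 1
            logger.warning("hold-out for %s failed: %s", target, exc)
    if n_failed:
        logger.warning("%d hold-out targets failed and were skipped", n_failed)
    return records


def summarize_cv(records) -> CVSummary:
    """Mean error, mean absolute error, and 50/80/95% empirical coverage."""
    records = list(records)
    if not records:
        raise ValueError("no CV records")
    err = np.array([r.predicted - r.observed for r in records])
    obs = np.array([r.observed for r in records])
    cov = {}
    for lev, lo, hi in (
        (0.50, "lower50", "upper50"),
        (0.80, "lower80", "upper80"),
        (0.95, "lower95", "upper95"),
    ):
        inside = [
            getattr(r, lo) <= o <= getattr(r, hi) for r, o in zip(records, obs)
        ]
        cov[lev] = float(np.mean(inside))
    return CVSummary(
        mean_error=float(err.mean()),
        mean_abs_error=float(np.abs(err).mean()),
        coverage50=cov[0.50],
        coverage80=cov[0.80],
        coverage95=cov[0.95],
        n_cells=len(records),
    )
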