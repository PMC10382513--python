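"""Stage 1: design-weighted direct estimates with design-based variances.

Each (area, year, survey[, stratum]) cell gets a Hajek (ratio) estimate of
the metric mean, a with-replacement linearised variance treating facilities
as primary sampling units within design strata, and the logit transform with
its delta-method variance.  These direct estimates and variances are the
observations of the stage-2 area-level smoothing models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "hajek_mean",
    "design_variance",
    "logit_with_delta_var",
    "build_direct_dataset",
    "direct_estimates",
]

#: columns of the direct-estimate table, in output order
DIRECT_COLUMNS = [
    "area_id", "year", "survey_id", "metric", "p_hat", "var_p", "n",
    "n_strata", "y_logit", "var_logit", "usable", "boundary_corrected",
]


def hajek_mean(values, weights) -> float:
    """Weighted mean sum(w*y)/sum(w); invariant to rescaling the weights."""
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != w.shape:
        raise ValueError("values and weights differ in length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return float(np.sum(w * y) / np.sum(w))


def design_variance(values, weights, strata=None) -> float:
    """With-replacement linearised variance of the Hajek mean.

    With z_hi = w_hi (y_hi - p_hat) / sum(w), the estimator is

        v = sum_h  n_h/(n_h - 1) * sum_i (z_hi - zbar_h)^2

    treating each facility as a PSU within its design stratum.  Strata with a
    single sampled facility are collapsed into one "certainty" stratum for
    variance estimation only; if that pooled stratum still has one member it
    contributes zero.
    """
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("design variance needs n >= 2")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if strata is None:
        strata = np.zeros(n, dtype=int)
    h = pd.Series(np.asarray(strata)).astype(str).to_numpy()

    # collapse singleton strata into one pooled certainty stratum
    counts = pd.Series(h).value_counts()
    singletons = set(counts[counts == 1].index)
    if singletons:
        h = np.where(np.isin(h, list(singletons)), "__certainty__", h)

    p_hat = hajek_mean(y, w)
    z = w * (y - p_hat) / w.sum()
    v = 0.0
    for lab in np.unique(h):
        zi = z[h == lab]
        n_h = zi.size
        if n_h < 2:
            continue
        v += n_h / (n_h - 1) * float(np.sum((zi - zi.mean()) ** 2))
    return v


def logit_with_delta_var(p_hat: float, var_p: float):
    """Logit transform with its delta-method variance var_p / (p(1-p))^2."""
    if not (0.0 < p_hat < 1.0):
        raise ValueError("p_hat must be strictly inside (0, 1); apply a correction first")
    if var_p < 0:
        raise ValueError("var_p must be >= 0")
    y = float(np.log(p_hat / (1.0 - p_hat)))
    return y, float(var_p / (p_hat * (1.0 - p_hat)) ** 2)


def _one_cell(sub: pd.DataFrame, value_col: str) -> dict:
    y = sub[value_col].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    n = len(sub)
    p_hat = hajek_mean(y, w)
    boundary = False
    if n >= 2:
        var_p = design_variance(y, w, sub["stratum"].to_numpy())
    else:
        var_p = np.nan
    if p_hat <= 0.0 or p_hat >= 1.0:
        # continuity correction so boundary cells survive with wide intervals
        boundary = True
        p_tilde = (n * p_hat + 0.5) / (n + 1)
        var_floor = p_tilde * (1 - p_tilde) / n
        var_p = max(var_p, var_floor) if np.isfinite(var_p) else var_p
        p_hat = p_tilde
    elif np.isfinite(var_p) and var_p < 1e-12:
        # all facilities tie at an interior value: floor the variance at the
        # binomial analogue so the cell does not enter with near-zero noise
        boundary = True
        var_p = p_hat * (1 - p_hat) / n
    usable = bool(n >= 2 and np.isfinite(var_p) and var_p > 0 and 0 < p_hat < 1)
    if usable:
        y_logit, var_logit = logit_with_delta_var(p_hat, var_p)
    else:
        y_logit, var_logit = np.nan, np.nan
    return {
        "p_hat": p_hat, "var_p": var_p, "n": n,
        "n_strata": int(sub["stratum"].nunique()),
        "y_logit": y_logit, "var_logit": var_logit,
        "usable": usable, "boundary_corrected": boundary,
    }


def direct_estimates(
    table: pd.DataFrame, metric: str, value_col: str, grouping: str | None = None
) -> pd.DataFrame:
    """Direct-estimate rows for one metric from a facility-level value table.

    ``table`` needs area_id, year, survey_id, stratum, weight and the metric
    value column.  ``grouping`` optionally adds a stratifier column (e.g.
    managing_authority) so public/private analyses reuse the same machinery.
    Rows lacking a weight or area are rejected with logged identifiers.
    """
    required = ["area_id", "year", "survey_id", "stratum", "weight", value_col]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    bad = table["weight"].isna() | (table["weight"] <= 0) | table["area_id"].isna()
    if bad.any():
        ids = table.loc[bad, "facility_id"] if "facility_id" in table.columns else bad.index[bad]
        logger.warning("rejecting %d rows with missing/invalid weight or area: %s",
                       int(bad.sum()), list(ids)[:10])
        table = table[~bad]
    keys = ["area_id", "year", "survey_id"] + ([grouping] if grouping else [])
    rows = []
    for key, sub in table.groupby(keys, sort=True):
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["metric"] = metric
        rec.update(_one_cell(sub, value_col))
        rows.append(rec)
    out = pd.DataFrame(rows)
    n_corr = int(out["boundary_corrected"].sum())
    if n_corr:
        logger.info("%s: continuity-corrected %d boundary cells", metric, n_corr)
    n_bad = int((~out["usable"]).sum())
    if n_bad:
        logger.info("%s: %d cells unusable (n<2 or degenerate variance)", metric, n_bad)
    cols = DIRECT_COLUMNS + ([grouping] if grouping else [])
    return out[[c for c in cols if c in out.columns]]


def build_direct_dataset(
    facility_metrics: pd.DataFrame,
    facility_process: pd.DataFrame | None = None,
    grouping: str | None = None,
) -> pd.DataFrame:
    """Direct estimates for both metrics, stacked into one table.

    ``facility_metrics`` holds one row per sampled facility with a
    ``readiness`` column; ``facility_process`` holds facility-mean process
    quality (column ``process_quality``) joined to the same design columns.
    Facility weights are used for both metrics (facility-mean process scores
    inherit the facility weight).
    """
    parts = [direct_estimates(facility_metrics, "readiness", "readiness", grouping)]
    if facility_process is not None and len(facility_process):
        parts.append(
            direct_estimates(facility_process, "process_quality", "process_quality", grouping)
        )
    return pd.concat(parts, ignore_index=True)
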