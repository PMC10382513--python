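"""Model comparison: WAIC, DIC and the log conditional predictive ordinate.

All three criteria are computed from the pointwise data log-likelihood
matrix (posterior draws x likelihood cells) of a fitted model; lower is
better for each.  WAIC is the primary selection criterion, with ties broken
by LCPO, then DIC, then the smallest model id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .inference import PosteriorDraws

__all__ = [
    "FitScore",
    "compute_waic",
    "compute_dic",
    "compute_lcpo",
    "score_fit",
    "select_best",
]


@dataclass(frozen=True)
class FitScore:
    model_id: int
    dic: float
    waic: float
    lcpo: float
    p_waic: float
    p_dic: float


def _check_ll(ll: np.ndarray) -> np.ndarray:
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2) x cells log-likelihood matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihoods")
    return ll


def compute_waic(loglik: np.ndarray) -> tuple[float, float]:
    """WAIC = -2 sum_i [ log mean_d exp(ll_di) - var_d(ll_di) ].

    Returns (waic, p_waic) where p_waic is the summed pointwise variance
    (the effective number of parameters).
    """
    ll = _check_ll(loglik)
    S = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    return float(-2.0 * np.sum(lppd - p_i)), float(p_i.sum())


def compute_dic(loglik_at_mean: np.ndarray, mean_deviance: float) -> tuple[float, float]:
    """DIC = mean deviance + p_D, with p_D = mean deviance - deviance at the
    posterior mean.  Returns (dic, p_d)."""
    d_hat = -2.0 * float(np.sum(loglik_at_mean))
    if not np.isfinite(d_hat) or not np.isfinite(mean_deviance):
        raise ValueError("non-finite deviance")
    p_d = mean_deviance - d_hat
    return mean_deviance + p_d, p_d


def compute_lcpo(loglik: np.ndarray, return_pointwise: bool = False):
    """Mean negative log conditional predictive ordinate.

    CPO_i is estimated by the importance-weighted harmonic mean
    1 / mean_d exp(-ll_di), with importance weights truncated at
    sqrt(S) times their mean (Ionides-style stabilisation) to control the
    heavy right tail of the raw harmonic-mean estimator.
    """
    ll = _check_ll(loglik)
    S = ll.shape[0]
    logw = -ll  # (S, n) raw importance log-weights
    log_wbar = logsumexp(logw, axis=0) - np.log(S)
    cap = log_wbar + 0.5 * np.log(S)
    logw_t = np.minimum(logw, cap[None, :])
    neg_log_cpo = logsumexp(logw_t, axis=0) - np.log(S)
    if return_pointwise:
        return float(neg_log_cpo.mean()), neg_log_cpo
    return float(neg_log_cpo.mean())


def score_fit(draws: PosteriorDraws) -> FitScore:
    """All three criteria from one fitted model's draws."""
    ll = draws.loglik
    waic, p_waic = compute_waic(ll)
    mean_dev = float(np.mean(-2.0 * ll.sum(axis=1)))
    mu_bar = draws.cell_means().mean(axis=0)
    ll_at_mean = norm.logpdf(draws.data.y, loc=mu_bar, scale=np.sqrt(draws.data.var))
    dic, p_d = compute_dic(ll_at_mean, mean_dev)
    lcpo = compute_lcpo(ll)
    return FitScore(
        model_id=draws.spec.model_id, dic=float(dic), waic=float(waic),
        lcpo=float(lcpo), p_waic=float(p_waic), p_dic=float(p_d),
    )


def select_best(scores) -> int:
    """Smallest WAIC wins; ties broken by LCPO, then DIC, then model id."""
    scores = list(scores)
    if not scores:
        raise ValueError("no candidate scores")
    best = min(scores, key=lambda s: (s.waic, s.lcpo, s.dic, s.model_id))
    return best.model_id
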