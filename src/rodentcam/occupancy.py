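"""Single-season occupancy models with constant or night-varying detection.

The model: each site is occupied with probability psi; on survey night t an
occupied site yields a detection with probability p (constant) or p_t
(night-varying).  The site likelihood is the zero-inflated Bernoulli
product

    L_s = psi * prod_t p_t^y_st (1 - p_t)^(1 - y_st)
          + (1 - psi) * 1[all y_st = 0],

with the product over the nights site s was actually surveyed (histories
may be ragged).  Maximum likelihood is found by quasi-Newton optimisation
on logit-transformed parameters with multiple starts; standard errors come
from the inverse observed information with the delta method, and Wald
intervals are formed on the logit scale and back-transformed so they stay
inside [0, 1].

The module also computes the cumulative probability of detecting an
occupied site at least once over n nights, P_n = 1 - prod_{t<=n}(1 - p_t),
and the number of nights needed before a string of non-detections supports
site-level absence at a chosen confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, xlogy
from statsmodels.tools.numdiff import approx_hess1

CONSTANT = "constant"
BY_NIGHT = "by_night"

MODEL_NAMES = {CONSTANT: "psi(.)p(.)", BY_NIGHT: "psi(.)p(night)"}

Z975 = 1.959963984540054


@dataclass
class OccupancyModelSpec:
    """Which detection structure to fit."""

    detection_structure: str = CONSTANT

    def __post_init__(self):
        if self.detection_structure not in (CONSTANT, BY_NIGHT):
            raise ValueError(
                f"detection_structure must be '{CONSTANT}' or '{BY_NIGHT}'"
            )


@dataclass
class OccupancyFit:
    """Maximum-likelihood occupancy fit."""

    name: str
    detection_structure: str
    psi: float
    p: np.ndarray                 # length 1 (constant) or T_max
    psi_se: float
    p_se: np.ndarray
    psi_ci: tuple[float, float]
    p_ci: np.ndarray              # (len(p), 2)
    loglik: float
    k: int
    n_sites: int
    n_nights: int
    converged: bool
    boundary: bool = False        # saturated or empty data; SEs undefined
    site_ids: list = field(default_factory=list)

    def p_full(self) -> np.ndarray:
        """Detection probability for every night 1..n_nights."""
        if self.p.size == 1:
            return np.repeat(self.p, self.n_nights)
        return self.p

    def to_dict(self) -> dict:
        return {
            "model": self.name,
            "psi": self.psi,
            "psi_se": self.psi_se,
            "psi_ci": list(self.psi_ci),
            "p": self.p.tolist(),
            "p_se": self.p_se.tolist(),
            "p_ci": self.p_ci.tolist(),
            "logLik": self.loglik,
            "K": self.k,
            "n_sites": self.n_sites,
            "n_nights": self.n_nights,
            "converged": self.converged,
            "boundary": self.boundary,
        }


def as_history_matrix(histories) -> tuple[np.ndarray, list]:
    """Coerce detection histories to a float matrix with NaN for missing.

    Accepts the wide site x night DataFrame produced by
    ``events.detection_histories`` (or any array-like of 0/1/NaN).
    """
    if isinstance(histories, pd.DataFrame):
        return histories.to_numpy(dtype=float), list(histories.index)
    arr = np.asarray(histories, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr, list(range(arr.shape[0]))


def _site_logliks(psi: float, p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Log site likelihoods for the zero-inflated Bernoulli model."""
    mask = ~np.isnan(y)
    yy = np.where(mask, y, 0.0)
    # log prod over observed nights of p^y (1-p)^(1-y)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(yy, p[None, :]) + xlogy(1.0 - yy, 1.0 - p[None, :])
    log_cond = np.where(mask, terms, 0.0).sum(axis=1)
    detected = np.nansum(y, axis=1) > 0
    with np.errstate(divide="ignore"):
        log_psi = np.log(psi) if psi > 0 else -np.inf
        log_1mpsi = np.log1p(-psi) if psi < 1 else -np.inf
    occ_term = log_psi + log_cond
    out = np.where(
        detected, occ_term, np.logaddexp(occ_term, log_1mpsi)
    )
    return out


def occupancy_loglik(psi: float, p, histories) -> float:
    """Log-likelihood of detection histories under (psi, p).

    ``p`` is a scalar (broadcast over nights) or a vector of length T_max;
    missing nights (NaN) are skipped.
    """
    y, _ = as_history_matrix(histories)
    if y.size == 0:
        raise ValueError("histories are empty")
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi must be in [0, 1], got {psi}")
    if np.any(p_arr < 0.0) or np.any(p_arr > 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p_arr.size == 1:
        p_arr = np.repeat(p_arr, y.shape[1])
    if p_arr.size != y.shape[1]:
        raise ValueError(
            f"p has length {p_arr.size} but histories span {y.shape[1]} nights"
        )
    return float(_site_logliks(psi, p_arr, y).sum())


def _neg_loglik_logit(params: np.ndarray, y: np.ndarray, constant_p: bool) -> float:
    psi = expit(params[0])
    p = expit(params[1:])
    if constant_p:
        p = np.repeat(p, y.shape[1])
    return -_site_logliks(psi, p, y).sum()


def _neg_loglik_grad_logit(
    params: np.ndarray, y: np.ndarray, constant_p: bool
) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the negative log-likelihood on the
    logit scale."""
    psi = expit(params[0])
    p = expit(params[1:])
    if constant_p:
        p = np.repeat(p, y.shape[1])
    mask = ~np.isnan(y)
    yy = np.where(mask, y, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(yy, p[None, :]) + xlogy(1.0 - yy, 1.0 - p[None, :])
    log_cond = np.where(mask, terms, 0.0).sum(axis=1)
    detected = np.nansum(y, axis=1) > 0
    nondet = ~detected
    C = np.exp(log_cond[nondet])                 # prod (1-p) over observed
    L0 = psi * C + (1.0 - psi)
    with np.errstate(divide="ignore"):
        log_psi = np.log(psi) if psi > 0 else -np.inf
    value = float(
        -(log_psi * detected.sum() + log_cond[detected].sum()
          + np.log(L0).sum())
    )
    # d/d logit(psi)
    g_a = (1.0 - psi) * detected.sum() + np.sum(
        psi * (1.0 - psi) * (C - 1.0) / L0
    )
    # d/d logit(p_t): detected sites m(y - p); non-detected -psi C p m / L
    m_det = mask[detected]
    g_p_det = np.sum(m_det * (yy[detected] - p[None, :]), axis=0)
    m_non = mask[nondet]
    g_p_non = -np.sum(
        (psi * C / L0)[:, None] * p[None, :] * m_non, axis=0
    )
    g_p = g_p_det + g_p_non
    if constant_p:
        g_p = np.array([g_p.sum()])
    return value, -np.concatenate([[g_a], g_p])


def fit_occupancy(
    histories,
    spec: OccupancyModelSpec | str = CONSTANT,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> OccupancyFit:
    """Fit psi(.)p(.) or psi(.)p(night) by maximum likelihood.

    Runs a quasi-Newton optimiser on logit-transformed parameters from
    several starting points (naive estimates, 0.5, random) and keeps the
    best; K is 2 for constant detection and T_max + 1 for night-varying.
    Saturated (all detected every night) and empty (no detections) data sit
    on the parameter boundary: the fit is returned exactly there with a
    ``boundary`` flag and undefined standard errors.
    """
    if isinstance(spec, str):
        spec = OccupancyModelSpec(spec)
    y, site_ids = as_history_matrix(histories)
    if y.size == 0 or not np.isfinite(np.nanmax(y)):
        raise ValueError("need at least one site with one observed night")
    n_sites, t_max = y.shape
    constant_p = spec.detection_structure == CONSTANT
    if not constant_p and t_max < 2:
        raise ValueError("night-varying detection needs >= 2 survey nights")
    k = 2 if constant_p else t_max + 1
    n_p = 1 if constant_p else t_max
    obs = ~np.isnan(y)
    detected_site = np.nansum(y, axis=1) > 0
    naive_psi = detected_site.mean()

    common = dict(
        detection_structure=spec.detection_structure,
        name=MODEL_NAMES[spec.detection_structure],
        k=k, n_sites=n_sites, n_nights=t_max, site_ids=site_ids,
    )
    if naive_psi == 0.0:
        # no detections anywhere: psi and p unidentifiable, boundary fit
        p0 = np.zeros(n_p)
        return OccupancyFit(
            psi=0.0, p=p0, psi_se=np.nan, p_se=np.full(n_p, np.nan),
            psi_ci=(np.nan, np.nan), p_ci=np.full((n_p, 2), np.nan),
            loglik=0.0, converged=True, boundary=True, **common,
        )
    if np.all(y[obs] == 1.0) and naive_psi == 1.0:
        # saturated: every surveyed night of every site detected
        p1 = np.ones(n_p)
        return OccupancyFit(
            psi=1.0, p=p1, psi_se=np.nan, p_se=np.full(n_p, np.nan),
            psi_ci=(np.nan, np.nan), p_ci=np.full((n_p, 2), np.nan),
            loglik=0.0, converged=True, boundary=True, **common,
        )

    def clip_logit(x):
        return logit(np.clip(x, 0.02, 0.98))

    # naive detection probability among detected sites
    det = y[detected_site]
    if constant_p:
        naive_p = np.array([np.nanmean(det)]) if det.size else np.array([0.5])
    else:
        with np.errstate(invalid="ignore"):
            naive_p = np.nanmean(det, axis=0)
        naive_p = np.where(np.isnan(naive_p), 0.5, naive_p)

    rng = np.random.default_rng(seed)
    starts = [
        np.concatenate([[clip_logit(naive_psi)], clip_logit(naive_p)]),
        np.zeros(1 + n_p),  # psi = p = 0.5
    ]
    while len(starts) < max(2, n_starts):
        starts.append(rng.normal(scale=1.5, size=1 + n_p))

    best = None
    for x0 in starts:
        res = minimize(
            _neg_loglik_grad_logit, x0, args=(y, constant_p),
            jac=True, method="BFGS", options={"gtol": tol, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    params = best.x
    psi_hat = float(expit(params[0]))
    p_hat = expit(params[1:])
    loglik = -float(best.fun)

    # observed information on the logit scale -> delta method to probabilities
    psi_se = np.nan
    p_se = np.full(n_p, np.nan)
    psi_ci = (np.nan, np.nan)
    p_ci = np.full((n_p, 2), np.nan)
    try:
        hess = approx_hess1(params, _neg_loglik_logit, args=(y, constant_p))
        cov = np.linalg.inv(hess)
        se_logit = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        if np.all(np.isfinite(se_logit)):
            lo = expit(params - Z975 * se_logit)
            hi = expit(params + Z975 * se_logit)
            grad = np.concatenate([[psi_hat * (1 - psi_hat)], p_hat * (1 - p_hat)])
            se_prob = se_logit * grad
            psi_se = float(se_prob[0])
            p_se = se_prob[1:]
            psi_ci = (float(lo[0]), float(hi[0]))
            p_ci = np.column_stack([lo[1:], hi[1:]])
    except np.linalg.LinAlgError:
        pass

    return OccupancyFit(
        psi=psi_hat, p=np.asarray(p_hat), psi_se=psi_se, p_se=np.asarray(p_se),
        psi_ci=psi_ci, p_ci=np.asarray(p_ci), loglik=loglik,
        converged=bool(best.success), boundary=False, **common,
    )


def cumulative_detection(
    p, p_lower=None, p_upper=None
) -> pd.DataFrame:
    """Cumulative detection probability P_n = 1 - prod_{i<=n}(1 - p_i).

    Optional per-night CI endpoints for p are propagated through the same
    monotone formula, giving bounds on P_n.  Returns a DataFrame with
    columns night, p, P and (when bounds are given) P_lower, P_upper.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if p.size == 0:
        raise ValueError("p vector is empty")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p must lie in [0, 1]")
    P = 1.0 - np.cumprod(1.0 - p)
    out = pd.DataFrame({"night": np.arange(1, p.size + 1), "p": p, "P": P})
    if p_lower is not None and p_upper is not None:
        lo = np.atleast_1d(np.asarray(p_lower, dtype=float))
        hi = np.atleast_1d(np.asarray(p_upper, dtype=float))
        out["P_lower"] = 1.0 - np.cumprod(1.0 - lo)
        out["P_upper"] = 1.0 - np.cumprod(1.0 - hi)
    return out


@dataclass
class NightsToConfidence:
    """Survey effort needed for confident absence.

    ``nights`` is the smallest n with P_n >= level, or None when the
    supplied nightly probabilities cannot reach the level (``reached`` is
    False and ``achieved`` reports the best attainable P).
    """

    nights: int | None
    achieved: float
    level: float

    @property
    def reached(self) -> bool:
        return self.nights is not None


def nights_to_confidence(
    p, level: float = 0.95, max_nights: int = 1000
) -> NightsToConfidence:
    """Smallest number of consecutive non-detection nights after which
    absence can be asserted with the given confidence.

    A scalar p uses the closed form ceil(log(1 - level) / log(1 - p)) (the
    scalar is treated as repeating indefinitely, up to ``max_nights``); a
    vector is scanned in night order and may not reach the level within its
    length.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p_arr < 0.0) or np.any(p_arr > 1.0):
        raise ValueError("p must lie in [0, 1]")
    scalar = np.isscalar(p) or p_arr.size == 1
    if scalar:
        ps = float(p_arr[0])
        if ps == 0.0:
            return NightsToConfidence(None, 0.0, level)
        if ps == 1.0:
            return NightsToConfidence(1, 1.0, level)
        n = int(np.ceil(np.log1p(-level) / np.log1p(-ps)))
        n = max(n, 1)
        if n > max_nights:
            return NightsToConfidence(
                None, 1.0 - (1.0 - ps) ** max_nights, level
            )
        return NightsToConfidence(n, 1.0 - (1.0 - ps) ** n, level)
    P = 1.0 - np.cumprod(1.0 - p_arr)
    idx = np.nonzero(P >= level)[0]
    if idx.size == 0:
        return NightsToConfidence(None, float(P[-1]), level)
    n = int(idx[0]) + 1
    return NightsToConfidence(n, float(P[n - 1]), level)


def compare_detection_models(
    fits: Sequence[OccupancyFit], n: int | None = None, criterion: str = "aic"
):
    """Information-criterion table across occupancy fits on one dataset.

    ``n`` (effective sample size for AICc) defaults to the common number of
    sites.  Shares the table machinery with the GLM candidate sets.
    """
    from rodentcam.model_selection import ic_table

    sizes = {f.n_sites for f in fits}
    if len(sizes) != 1:
        raise ValueError(f"fits come from different datasets: n_sites {sizes}")
    if n is None:
        n = sizes.pop()
    return ic_table(fits, n=n, criterion=criterion)
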