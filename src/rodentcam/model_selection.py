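"""Negative binomial GLMs, information criteria and model averaging.

Activity counts from camera traps are overdispersed, so candidate models
for site-level event counts are negative binomial (NB2: variance
mu + mu^2/theta) regressions with a log link and an offset for survey
effort (log nights observed).  An a-priori candidate set is compared by
AICc; Akaike weights give the proportional support for each model and,
where selection uncertainty exists, coefficients are model-averaged across
the set with unconditional standard errors.

Fitting alternates statsmodels' IRLS for the regression coefficients at
fixed dispersion with univariate maximum likelihood for theta, the same
scheme as the classic glm.nb estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054
LOG_THETA_MAX = 18.0   # theta ~ 6.6e7: effectively Poisson
LOG_THETA_MIN = -7.0


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: main effects plus optional pairwise interactions.

    Interactions are hierarchical: every interaction's main effects must be
    present in ``terms``.
    """

    name: str
    terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ValueError(
                    f"interaction {a}*{b} requires both main effects in {self.name!r}"
                )

    @property
    def columns(self) -> list[str]:
        return list(self.terms) + [f"{a}*{b}" for a, b in self.interactions]


def parse_model_name(name: str) -> ModelSpec:
    """Parse a compact model label like ``"C_gt1m+BD+C_gt1m*BD"``.

    ``"Constant"`` denotes the intercept-only model.
    """
    if name.strip().lower() == "constant":
        return ModelSpec(name=name, terms=(), interactions=())
    terms: list[str] = []
    inters: list[tuple[str, str]] = []
    for part in name.split("+"):
        part = part.strip()
        if "*" in part:
            a, b = (x.strip() for x in part.split("*"))
            inters.append((a, b))
        elif part:
            terms.append(part)
    return ModelSpec(name=name, terms=tuple(terms), interactions=tuple(inters))


#: a-priori candidate model sets for the two rodents.  The house-mouse set
#: adds black-rat activity (RR) as a covariate to test interference.
BLACK_RAT_MODELS = (
    "C_gt1m",
    "C_gt1m+BD",
    "C_gt1m+BD+C_gt1m*BD",
    "Poa+Tetra+Rhag",
    "Constant",
    "C10_40",
    "BD",
    "Atden",
    "Emden",
    "C10_40+BD",
    "C10_40+BD+C10_40*BD",
    "Emden+C10_40+Emden*C10_40",
)
HOUSE_MOUSE_MODELS = (
    "C_gt1m",
    "Poa+Tetra+Rhag",
    "C_gt1m+BD",
    "C10_40",
    "Constant",
    "Atden",
    "Emden+C10_40+Emden*C10_40",
    "C_gt1m+BD+C_gt1m*BD",
    "C10_40+BD",
    "Emden",
    "RR",
    "BD",
    "C10_40+BD+C10_40*BD",
)


def candidate_sets(species: str) -> list[ModelSpec]:
    """The a-priori candidate model set for ``"black_rat"`` or
    ``"house_mouse"``."""
    key = species.strip().lower().replace(" ", "_")
    if key == "black_rat":
        return [parse_model_name(n) for n in BLACK_RAT_MODELS]
    if key == "house_mouse":
        return [parse_model_name(n) for n in HOUSE_MOUSE_MODELS]
    raise ValueError(f"unknown species {species!r}")


@dataclass
class NBFit:
    """A fitted negative binomial GLM."""

    spec: ModelSpec
    params: pd.Series          # coefficients incl. intercept
    bse: pd.Series
    theta: float
    loglik: float
    k: int                     # coefficients + dispersion
    n: int
    converged: bool
    theta_at_bound: bool = False

    @property
    def name(self) -> str:
        return self.spec.name


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood with mean mu and dispersion theta."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(
        np.sum(
            gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def design_matrix(spec: ModelSpec, covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + main effects + products for the interactions."""
    X = pd.DataFrame({"Intercept": np.ones(len(covariates))},
                     index=covariates.index)
    for term in spec.terms:
        if term not in covariates.columns:
            raise ValueError(f"covariate {term!r} not found for model {spec.name!r}")
        X[term] = covariates[term].to_numpy(dtype=float)
    for a, b in spec.interactions:
        X[f"{a}*{b}"] = X[a] * X[b]
    return X


def fit_nb_glm(
    spec: ModelSpec | str,
    response,
    covariates: pd.DataFrame,
    offset=None,
    max_iter: int = 100,
    tol: float = 1e-9,
    fixed_theta: float | None = None,
) -> NBFit:
    """Fit a log-link NB regression for event counts.

    ``response`` are non-negative integer counts (per-site totals in the
    default analysis), ``offset`` the log of nights observed (or None for
    no effort adjustment).  Coefficients are estimated by iteratively
    reweighted least squares at fixed theta, alternated with univariate
    maximum likelihood for theta, until the log-likelihood changes by less
    than ``tol`` (relative).  K counts the dispersion parameter.

    ``fixed_theta`` holds the dispersion at a known value instead of
    profiling it (theta very large reduces the model to Poisson); K still
    counts it.
    """
    if isinstance(spec, str):
        spec = parse_model_name(spec)
    y = np.asarray(response, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X = design_matrix(spec, covariates)
    if len(X) != y.size:
        raise ValueError("response and covariates differ in length")
    off = None if offset is None else np.asarray(offset, dtype=float)

    if fixed_theta is not None:
        if not fixed_theta > 0:
            raise ValueError("fixed_theta must be positive")
        theta = float(fixed_theta)
    else:
        # moment start for theta
        mean, var = y.mean(), y.var()
        theta = mean**2 / max(var - mean, 1e-6) if var > mean else 50.0
        theta = float(
            np.clip(theta, np.exp(LOG_THETA_MIN), np.exp(LOG_THETA_MAX))
        )

    loglik_old = -np.inf
    converged = False
    res = None
    for _ in range(max_iter):
        model = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=1.0 / theta),
            offset=off,
        )
        res = model.fit(tol=1e-10, maxiter=300)
        mu = np.asarray(res.mu, dtype=float)

        if fixed_theta is not None:
            loglik = nb_loglik(y, mu, theta)
        else:
            def neg_ll(log_theta):
                return -nb_loglik(y, mu, np.exp(log_theta))

            opt = minimize_scalar(
                neg_ll, bounds=(LOG_THETA_MIN, LOG_THETA_MAX),
                method="bounded", options={"xatol": 1e-10},
            )
            theta = float(np.exp(opt.x))
            loglik = -float(opt.fun)
        if abs(loglik - loglik_old) < tol * (abs(loglik_old) + 1.0):
            converged = True
            break
        loglik_old = loglik
    else:
        logger.warning("NB fit for model %r did not converge", spec.name)

    theta_at_bound = abs(np.log(theta) - LOG_THETA_MAX) < 1e-6
    return NBFit(
        spec=spec,
        params=pd.Series(np.asarray(res.params, dtype=float), index=X.columns),
        bse=pd.Series(np.asarray(res.bse, dtype=float), index=X.columns),
        theta=theta,
        loglik=loglik,
        k=X.shape[1] + 1,
        n=y.size,
        converged=converged,
        theta_at_bound=theta_at_bound,
    )


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, -2 logLik + 2K."""
    return -2.0 * loglik + 2.0 * k


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2K(K+1)/(n-K-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc requires n > K + 1 (n={n}, K={k})")
    return aic(loglik, k) + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(delta) -> np.ndarray:
    """Akaike weights from criterion differences.

    Deltas are rebased to min 0 internally, so any constant shift of the
    criterion leaves the weights unchanged.
    """
    d = np.asarray(delta, dtype=float)
    if d.size == 0:
        raise ValueError("empty delta vector")
    d = d - d.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def ic_table(
    fits: Sequence, n: int | None = None, criterion: str = "aicc"
) -> pd.DataFrame:
    """Candidate-model comparison table.

    ``fits`` need a ``name``, ``loglik`` and ``k`` (NBFit and OccupancyFit
    both qualify).  Emits both AIC and AICc columns; ``criterion`` chooses
    which one drives delta, weight and ordering.  ``n`` is the effective
    sample size for AICc (defaults to each fit's own n).
    """
    if criterion not in ("aic", "aicc"):
        raise ValueError(f"criterion must be 'aic' or 'aicc', got {criterion!r}")
    if len(fits) == 0:
        raise ValueError("no fits supplied")
    names = [f.name for f in fits]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate model names in {names}")
    rows = []
    for f in fits:
        n_eff = n if n is not None else getattr(f, "n", getattr(f, "n_sites", None))
        rows.append(
            {
                "Model": f.name,
                "K": f.k,
                "logLik": f.loglik,
                "minus2LL": -2.0 * f.loglik,
                "AIC": aic(f.loglik, f.k),
                "AICc": aicc(f.loglik, f.k, n_eff),
            }
        )
    tab = pd.DataFrame(rows)
    crit = tab["AIC"] if criterion == "aic" else tab["AICc"]
    tab["delta"] = crit - crit.min()
    tab["weight"] = akaike_weights(tab["delta"].to_numpy())
    tab = tab.sort_values(
        ["delta", "K", "Model"], kind="mergesort"
    ).reset_index(drop=True)
    tab.attrs["criterion"] = criterion
    return tab


def model_average(
    table: pd.DataFrame,
    fits: Sequence[NBFit],
    include_intercept: bool = False,
    conditional: bool = False,
) -> pd.DataFrame:
    """Model-averaged coefficients across a candidate set.

    Full averaging with shrinkage by default: a model that excludes a term
    contributes beta = 0 with SE 0, so rarely supported terms shrink toward
    zero.  ``conditional`` averages only over the models containing each
    term (weights renormalised).  The unconditional standard error follows
    the information-theoretic form

        SE = sum_i w_i * sqrt(SE_i^2 + (beta_i - beta_bar)^2)

    and the relative importance of a term is the summed weight of the
    models containing it.
    """
    weights = dict(zip(table["Model"], table["weight"]))
    missing = [f.name for f in fits if f.name not in weights]
    if missing:
        raise ValueError(f"fits not present in IC table: {missing}")
    terms: list[str] = []
    for f in fits:
        for t in f.params.index:
            if t == "Intercept" and not include_intercept:
                continue
            if t not in terms:
                terms.append(t)
    if not terms:
        raise ValueError("no coefficients to average")
    rows = []
    for term in terms:
        w_in = sum(weights[f.name] for f in fits if term in f.params.index)
        betas, ses, ws = [], [], []
        for f in fits:
            w = weights[f.name]
            if term in f.params.index:
                betas.append(f.params[term])
                ses.append(f.bse[term])
                ws.append(w)
            elif not conditional:
                betas.append(0.0)
                ses.append(0.0)
                ws.append(w)
        betas = np.asarray(betas)
        ses = np.asarray(ses)
        ws = np.asarray(ws)
        if conditional:
            if ws.sum() == 0:
                raise ValueError(f"term {term!r} only occurs in zero-weight models")
            ws = ws / ws.sum()
        beta_bar = float(np.sum(ws * betas))
        se_u = float(np.sum(ws * np.sqrt(ses**2 + (betas - beta_bar) ** 2)))
        rows.append(
            {
                "term": term,
                "estimate": beta_bar,
                "se": se_u,
                "lower": beta_bar - Z975 * se_u,
                "upper": beta_bar + Z975 * se_u,
                "importance": float(w_in),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["averaging"] = "conditional" if conditional else "full"
    return out


def selection_uncertain(table: pd.DataFrame, threshold: float = 0.9) -> bool:
    """Model-selection uncertainty trigger: top weight below ``threshold``."""
    return float(table["weight"].iloc[0]) < threshold
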