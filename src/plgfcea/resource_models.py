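"""Adjusted mean resource use per subgroup and arm.

Each resource category is modelled with a generalised linear mixed model
whose covariates are the nine PlGF x diagnosis subgroup cells, the trial
arm (with an arm x subgroup interaction so every cell has its own arm
contrast), a linear secular-time term, and a random intercept for
centre — the standard adjustment set for a stepped-wedge design.

The default family is a two-part (hurdle) model: a mixed logistic model
for whether a woman used the service at all, and a zero-truncated
negative binomial (or Poisson) mixed model for the positive quantity.
One-part negative binomial and Poisson mixed models are available as
alternative candidates; the best family per category is chosen by AIC.
When no candidate converges the category is re-analysed with a plain
logistic regression for admission plus a linear regression for length
of stay among the admitted — the classical fallback for sparse neonatal
intensive-care data.

The centre random intercept is integrated out by adaptive Gauss-Hermite
quadrature. The marginal likelihood is maximised with an analytic
gradient for a fixed set of quadrature nodes, re-adapting the nodes
(posterior mode and curvature per cluster) in an outer loop until the
likelihood is stable. No pre-installed Python library fits mixed hurdle
count models, so the engine is implemented here directly.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import digamma, expit, gammaln, logsumexp

from .schema import ARMS, CATEGORIES, SUBGROUPS, subgroup_label

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MixedFit",
    "TwoPartFit",
    "FallbackFit",
    "NoConvergedModelError",
    "build_design_matrix",
    "cell_covariates",
    "fit_glmm",
    "select_model",
    "fit_fallback",
    "adjusted_means",
    "fit_all_categories",
    "fit_delivery_cost",
    "write_adjusted_means",
    "read_adjusted_means",
]

TWO_PART_FAMILIES = ("two_part_truncNB", "two_part_truncPoisson")
ONE_PART_FAMILIES = ("negative_binomial", "poisson")
DEFAULT_CANDIDATES = TWO_PART_FAMILIES + ONE_PART_FAMILIES

_ETA_MAX = 30.0


class NoConvergedModelError(RuntimeError):
    """No candidate family converged; the category needs the fallback."""


def _quiet(fn):
    """Silence benign floating-point warnings from extreme linear
    predictors explored during optimisation (they resolve to finite,
    guarded values)."""

    @functools.wraps(fn)
    def wrapper(*args, **kwargs):
        with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
            return fn(*args, **kwargs)

    return wrapper


# ---------------------------------------------------------------------------
# family log-likelihoods (per observation, as functions of eta = link scale)
# ---------------------------------------------------------------------------


def _clip_eta(eta):
    return np.clip(eta, -_ETA_MAX, _ETA_MAX)


def _log1mexp(x):
    """log(1 - exp(x)) for x < 0, stable near 0."""
    return np.log(-np.expm1(np.minimum(x, -1e-300)))


def _ll_logistic(y, eta, disp):
    return y * eta - np.logaddexp(0.0, eta)


def _d1_logistic(y, eta, disp):
    return y - expit(eta)


def _ll_poisson(y, eta, disp):
    eta = _clip_eta(eta)
    return y * eta - np.exp(eta) - gammaln(y + 1.0)


def _d1_poisson(y, eta, disp):
    return y - np.exp(_clip_eta(eta))


def _ll_trunc_poisson(y, eta, disp):
    eta = _clip_eta(eta)
    mu = np.exp(eta)
    return _ll_poisson(y, eta, disp) - _log1mexp(-mu)


def _d1_trunc_poisson(y, eta, disp):
    mu = np.exp(_clip_eta(eta))
    small = np.minimum(mu, 50.0)
    correction = np.where(mu > 50.0, 0.0, small / np.expm1(small))
    return y - mu - correction


def _ll_nb(y, eta, k):
    eta = _clip_eta(eta)
    mu = np.exp(eta)
    return (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1.0)
        + k * (np.log(k) - np.log(k + mu))
        + y * (eta - np.log(k + mu))
    )


def _d1_nb(y, eta, k):
    mu = np.exp(_clip_eta(eta))
    return y - (y + k) * mu / (k + mu)


def _dk_nb(y, eta, k):
    mu = np.exp(_clip_eta(eta))
    return (
        digamma(y + k)
        - digamma(k)
        + np.log(k)
        + 1.0
        - np.log(k + mu)
        - (k + y) / (k + mu)
    )


def _ll_trunc_nb(y, eta, k):
    eta = _clip_eta(eta)
    mu = np.exp(eta)
    lp0 = k * (np.log(k) - np.log(k + mu))
    return _ll_nb(y, eta, k) - _log1mexp(lp0)


def _d1_trunc_nb(y, eta, k):
    mu = np.exp(_clip_eta(eta))
    lp0 = k * (np.log(k) - np.log(k + mu))
    one_minus_p0 = -np.expm1(lp0)  # stable as mu -> 0
    p0 = np.exp(lp0)
    return _d1_nb(y, eta, k) - p0 * k * mu / (one_minus_p0 * (k + mu))


def _dk_trunc_nb(y, eta, k):
    mu = np.exp(_clip_eta(eta))
    lp0 = k * (np.log(k) - np.log(k + mu))
    one_minus_p0 = -np.expm1(lp0)
    p0 = np.exp(lp0)
    dp0 = p0 * (np.log(k) + 1.0 - np.log(k + mu) - k / (k + mu))
    return _dk_nb(y, eta, k) + dp0 / one_minus_p0


def _ll_gamma(y, eta, alpha):
    eta = _clip_eta(eta)
    return (
        alpha * np.log(alpha)
        - gammaln(alpha)
        + (alpha - 1.0) * np.log(y)
        - alpha * eta
        - alpha * y * np.exp(-eta)
    )


def _d1_gamma(y, eta, alpha):
    return alpha * (y * np.exp(-_clip_eta(eta)) - 1.0)


def _da_gamma(y, eta, alpha):
    eta = _clip_eta(eta)
    return np.log(alpha) + 1.0 - digamma(alpha) + np.log(y) - eta - y * np.exp(-eta)


@dataclass(frozen=True)
class _Family:
    name: str
    ll: callable
    d1: callable
    ddisp: callable | None = None  # derivative wrt the dispersion itself


_FAMILIES = {
    "logistic": _Family("logistic", _ll_logistic, _d1_logistic),
    "poisson": _Family("poisson", _ll_poisson, _d1_poisson),
    "truncPoisson": _Family("truncPoisson", _ll_trunc_poisson, _d1_trunc_poisson),
    "negative_binomial": _Family("negative_binomial", _ll_nb, _d1_nb, _dk_nb),
    "truncNB": _Family("truncNB", _ll_trunc_nb, _d1_trunc_nb, _dk_trunc_nb),
    "gamma_log": _Family("gamma_log", _ll_gamma, _d1_gamma, _da_gamma),
}


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

_REFERENCE = SUBGROUPS[0]  # PlGF>100 x normal


def build_design_matrix(
    records: pd.DataFrame, interaction: bool = True
) -> tuple[np.ndarray, list[str], float]:
    """Covariate matrix: intercept, 8 subgroup dummies (reference is the
    PlGF>100 x normal cell), arm, arm x subgroup interaction and the
    step index centred at its sample mean."""
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["const"]
    band = records["plgf_category"].to_numpy()
    dx = records["diagnosis"].to_numpy()
    arm = (records["arm"].to_numpy() == "revealed").astype(float)
    for b, d in SUBGROUPS:
        if (b, d) == _REFERENCE:
            continue
        ind = ((band == b) & (dx == d)).astype(float)
        cols.append(ind)
        names.append(f"sub[{subgroup_label(b, d)}]")
    cols.append(arm)
    names.append("arm")
    if interaction:
        for b, d in SUBGROUPS:
            if (b, d) == _REFERENCE:
                continue
            ind = ((band == b) & (dx == d)).astype(float)
            cols.append(ind * arm)
            names.append(f"arm:sub[{subgroup_label(b, d)}]")
    time_center = float(records["step"].mean())
    cols.append(records["step"].to_numpy() - time_center)
    names.append("time")
    return np.column_stack(cols), names, time_center


def cell_covariates(names: Sequence[str], band: str, dx: str, arm: str) -> np.ndarray:
    """Covariate row for a subgroup x arm cell, at centred time 0 and
    random effect 0 (the conditional prediction point)."""
    lab = subgroup_label(band, dx)
    a = 1.0 if arm == "revealed" else 0.0
    x = np.zeros(len(names))
    for j, name in enumerate(names):
        if name == "const":
            x[j] = 1.0
        elif name == f"sub[{lab}]":
            x[j] = 1.0
        elif name == "arm":
            x[j] = a
        elif name == f"arm:sub[{lab}]":
            x[j] = a
    return x


# ---------------------------------------------------------------------------
# mixed-model engine
# ---------------------------------------------------------------------------


@dataclass
class MixedFit:
    """One fitted GLMM component with a centre random intercept."""

    family: str
    coef: np.ndarray
    coef_names: list[str]
    pinned: np.ndarray
    dispersion: float | None
    sigma_c: float
    cov: np.ndarray  # over the active parameter vector (see theta_names)
    theta_names: list[str]
    loglik: float
    aic: float
    n_params: int
    nobs: int
    n_quad: int
    converged: bool

    @property
    def theta(self) -> np.ndarray:
        parts = [self.coef[~self.pinned]]
        if self.dispersion is not None:
            parts.append([np.log(self.dispersion)])
        if "log_sigma" in self.theta_names:
            parts.append([np.log(max(self.sigma_c, 1e-12))])
        return np.concatenate([np.atleast_1d(p) for p in parts])

    def coef_from_theta(self, theta: np.ndarray) -> np.ndarray:
        full = np.zeros_like(self.coef)
        full[~self.pinned] = theta[: int((~self.pinned).sum())]
        return full

    def dispersion_from_theta(self, theta: np.ndarray) -> float | None:
        if self.dispersion is None:
            return None
        return float(np.exp(theta[int((~self.pinned).sum())]))


@_quiet
def _posterior_modes(y, eta0, cluster_idx, n_clusters, fam, disp, sigma, u_init):
    """Laplace step: mode and curvature of each cluster's random-effect
    posterior, used to place the adaptive quadrature nodes."""
    u = u_init.copy()
    inv_s2 = 1.0 / sigma**2
    eps = 1e-5
    for _ in range(50):
        eta = eta0 + u[cluster_idx]
        d1 = fam.d1(y, eta, disp)
        g1 = np.bincount(cluster_idx, weights=d1, minlength=n_clusters) - u * inv_s2
        d2 = (fam.d1(y, eta + eps, disp) - fam.d1(y, eta - eps, disp)) / (2 * eps)
        g2 = np.bincount(cluster_idx, weights=d2, minlength=n_clusters) - inv_s2
        g2 = np.minimum(g2, -1e-8)
        step = np.clip(g1 / g2, -2.0, 2.0)
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[cluster_idx]
    d2 = (fam.d1(y, eta + eps, disp) - fam.d1(y, eta - eps, disp)) / (2 * eps)
    g2 = np.bincount(cluster_idx, weights=d2, minlength=n_clusters) - inv_s2
    h = np.maximum(-g2, 1e-8)
    return u, h


@_quiet
def _fit_mixed(
    y: np.ndarray,
    X: np.ndarray,
    cluster: np.ndarray,
    family: str,
    n_quad: int = 7,
    max_outer: int = 25,
    tol: float = 1e-8,
    coef_names: list[str] | None = None,
) -> MixedFit:
    """Maximum marginal likelihood for one GLMM component.

    Adaptive Gauss-Hermite quadrature over the cluster random intercept;
    L-BFGS-B with analytic gradients on a fixed node set, with nodes
    re-adapted in an outer loop.
    """
    from scipy.optimize import minimize

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n == 0:
        raise ValueError("no observations to fit")
    codes, _ = pd.factorize(pd.Series(cluster), sort=True)
    cluster_idx = codes.astype(int)
    C = int(cluster_idx.max()) + 1
    fam = _FAMILIES[family]
    has_disp = fam.ddisp is not None
    if coef_names is None:
        coef_names = [f"x{j}" for j in range(p)]

    pinned = (X == 0).all(axis=0)
    Xf = X[:, ~pinned]
    pf = Xf.shape[1]

    # moment starting values
    if family == "logistic":
        m = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        b0 = np.log(m / (1 - m))
    else:
        b0 = float(np.log(max(y.mean(), 1e-3)))
    beta0 = np.zeros(pf)
    free_names = [nm for nm, pin in zip(coef_names, pinned) if not pin]
    if "const" in free_names:
        beta0[free_names.index("const")] = b0
    theta0 = list(beta0)
    theta_names = list(free_names)
    if has_disp:
        if family == "gamma_log":
            cv2 = float(np.var(y) / np.mean(y) ** 2) if np.var(y) > 0 else 1.0
            theta0.append(np.log(max(1.0 / max(cv2, 1e-6), 1e-2)))
        else:
            theta0.append(0.0)
        theta_names.append("log_disp")
    sigma_active = C >= 2
    if sigma_active:
        theta0.append(np.log(0.2))
        theta_names.append("log_sigma")
    theta0 = np.array(theta0)

    z, w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w)

    def unpack(theta):
        beta = theta[:pf]
        disp = np.exp(np.clip(theta[pf], -12.0, 12.0)) if has_disp else None
        if sigma_active:
            sigma = float(np.exp(np.clip(theta[-1], -18.0, 2.0)))
        else:
            sigma = 1e-8
        return beta, disp, sigma

    def nll_grad(theta, U, log_const):
        beta, disp, sigma = unpack(theta)
        eta0 = Xf @ beta
        eta = eta0[:, None] + U[cluster_idx, :]
        ll = fam.ll(y[:, None], eta, disp)
        S = np.zeros((C, n_quad))
        np.add.at(S, cluster_idx, ll)
        logphi = -0.5 * np.log(2 * np.pi) - np.log(sigma) - U**2 / (2 * sigma**2)
        A = logw[None, :] + z[None, :] ** 2 + log_const[:, None] + S + logphi
        M = logsumexp(A, axis=1)
        nll = -float(M.sum())
        P = np.exp(A - M[:, None])
        Pobs = P[cluster_idx, :]
        d1 = fam.d1(y[:, None], eta, disp)
        r = (Pobs * d1).sum(axis=1)
        grad = np.empty_like(theta)
        grad[:pf] = -(Xf.T @ r)
        pos = pf
        if has_disp:
            dd = fam.ddisp(y[:, None], eta, disp)
            D = np.zeros((C, n_quad))
            np.add.at(D, cluster_idx, dd)
            grad[pos] = -float((P * D).sum()) * disp
            pos += 1
        if sigma_active:
            # derivative wrt log sigma
            dphi = U**2 / sigma**2 - 1.0
            grad[pos] = -float((P * dphi).sum())
        if not (np.isfinite(nll) and np.all(np.isfinite(grad))):
            return 1e30, np.zeros_like(theta)
        return nll, grad

    theta = theta0
    u_hat = np.zeros(C)
    last_nll = np.inf
    res = None
    outer_ok = False
    for _ in range(max_outer):
        beta, disp, sigma = unpack(theta)
        u_hat, h = _posterior_modes(
            y, Xf @ beta, cluster_idx, C, fam, disp, sigma, u_hat
        )
        U = u_hat[:, None] + np.sqrt(2.0 / h)[:, None] * z[None, :]
        log_const = 0.5 * np.log(2.0 / h)
        res = minimize(
            nll_grad,
            theta,
            args=(U, log_const),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        theta = res.x
        if abs(last_nll - res.fun) < tol * (abs(res.fun) + 1.0):
            outer_ok = True
            break
        last_nll = res.fun

    beta, disp, sigma = unpack(theta)
    # a restart exactly at the optimum can abort its line search with an
    # "abnormal" status; a vanishing gradient still counts as converged
    _, g_final = nll_grad(theta, U, log_const)
    converged = outer_ok and bool(
        res.success or res.status == 0 or np.abs(g_final).max() < 1e-2
    )

    # observed information by central differences of the analytic gradient
    dim = len(theta)
    H = np.zeros((dim, dim))
    for j in range(dim):
        hstep = 1e-5 * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += hstep
        tm = theta.copy()
        tm[j] -= hstep
        _, gp = nll_grad(tp, U, log_const)
        _, gm = nll_grad(tm, U, log_const)
        H[j, :] = (gp - gm) / (2 * hstep)
    H = 0.5 * (H + H.T)
    cov = np.linalg.pinv(H)

    coef_full = np.zeros(p)
    coef_full[~pinned] = beta
    loglik = -float(res.fun)
    n_params = pf + (1 if has_disp else 0) + (1 if sigma_active else 0)
    return MixedFit(
        family=family,
        coef=coef_full,
        coef_names=list(coef_names),
        pinned=pinned,
        dispersion=float(disp) if has_disp else None,
        sigma_c=float(sigma),
        cov=cov,
        theta_names=theta_names,
        loglik=loglik,
        aic=2.0 * n_params - 2.0 * loglik,
        n_params=n_params,
        nobs=n,
        n_quad=n_quad,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# model specs and public fitting operations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Candidate family plus the fixed covariate/adjustment structure."""

    family: str = "two_part_truncNB"
    n_quad: int = 7
    interaction: bool = True


@dataclass
class TwoPartFit:
    """Hurdle fit: mixed logistic use part + mixed truncated count part."""

    family: str
    part1: MixedFit
    part2: MixedFit
    coef_names: list[str]
    time_center: float

    @property
    def loglik(self) -> float:
        return self.part1.loglik + self.part2.loglik

    @property
    def n_params(self) -> int:
        return self.part1.n_params + self.part2.n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def converged(self) -> bool:
        return self.part1.converged and self.part2.converged

    @property
    def dispersion(self) -> float | None:
        return self.part2.dispersion


@dataclass
class OnePartFit:
    family: str
    part: MixedFit
    coef_names: list[str]
    time_center: float

    @property
    def loglik(self):
        return self.part.loglik

    @property
    def n_params(self):
        return self.part.n_params

    @property
    def aic(self):
        return self.part.aic

    @property
    def converged(self):
        return self.part.converged


def fit_glmm(records: pd.DataFrame, category: str, spec: ModelSpec | None = None):
    """Fit one candidate family for one resource category.

    Returns a :class:`TwoPartFit` for hurdle families, otherwise a
    :class:`OnePartFit`. Non-convergence is reported through the
    ``converged`` flag, never as an exception.
    """
    if spec is None:
        spec = ModelSpec()
    if category not in records.columns:
        raise ValueError(f"category {category!r} not present in records")
    X, names, time_center = build_design_matrix(records, spec.interaction)
    y = records[category].to_numpy(dtype=float)
    cluster = records["cluster"].to_numpy()
    if spec.family in TWO_PART_FAMILIES:
        part1 = _fit_mixed(
            (y > 0).astype(float), X, cluster, "logistic", spec.n_quad, coef_names=names
        )
        pos = y > 0
        fam2 = "truncNB" if spec.family == "two_part_truncNB" else "truncPoisson"
        if pos.sum() < 2:
            raise NoConvergedModelError(
                f"too few positive observations for {category}"
            )
        part2 = _fit_mixed(
            y[pos], X[pos], cluster[pos], fam2, spec.n_quad, coef_names=names
        )
        return TwoPartFit(spec.family, part1, part2, names, time_center)
    if spec.family in ONE_PART_FAMILIES:
        part = _fit_mixed(y, X, cluster, spec.family, spec.n_quad, coef_names=names)
        return OnePartFit(spec.family, part, names, time_center)
    raise ValueError(f"unknown family {spec.family!r}")


def _pick(candidates):
    """AIC selection among converged fits; ties go to fewer parameters."""
    converged = [(spec, fit) for spec, fit in candidates if fit.converged]
    if not converged:
        raise NoConvergedModelError("no candidate model converged")
    return min(converged, key=lambda sf: (round(sf[1].aic, 9), sf[1].n_params))


def select_model(
    records: pd.DataFrame,
    category: str,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    n_quad: int = 7,
):
    """Fit every candidate family and return ``(spec, fit)`` with minimal
    AIC among the converged fits. Raises
    :class:`NoConvergedModelError` when nothing converges (the caller
    escalates to :func:`fit_fallback`)."""
    fits = []
    for fam in candidates:
        spec = ModelSpec(family=fam, n_quad=n_quad)
        try:
            fit = fit_glmm(records, category, spec)
        except NoConvergedModelError:
            continue
        fits.append((spec, fit))
    if not fits:
        raise NoConvergedModelError("no candidate model could be fitted")
    return _pick(fits)


# ---------------------------------------------------------------------------
# fallback: logistic admission + linear length of stay
# ---------------------------------------------------------------------------


@dataclass
class FallbackFit:
    """Logistic admission-probability model plus linear days-if-admitted
    model (no random effect), for categories where the mixed hurdle
    model does not converge."""

    family: str
    logit_res: object
    linear_res: object
    coef_names: list[str]
    time_center: float
    zero_cells: set = field(default_factory=set)

    converged: bool = True


def fit_fallback(records: pd.DataFrame, category: str) -> FallbackFit:
    X, names, time_center = build_design_matrix(records)
    y = records[category].to_numpy(dtype=float)
    adm = (y > 0).astype(float)
    zero_cells = set()
    for b, d in SUBGROUPS:
        for arm in ARMS:
            mask = (
                (records["plgf_category"] == b)
                & (records["diagnosis"] == d)
                & (records["arm"] == arm)
            )
            if not mask.any() or y[mask.to_numpy()].sum() == 0:
                zero_cells.add((b, d, arm))
    logit_res = sm.GLM(adm, X, family=sm.families.Binomial()).fit(maxiter=200)
    pos = y > 0
    if pos.sum() >= 2:
        linear_res = sm.OLS(y[pos], X[pos]).fit()
    else:
        linear_res = None
    return FallbackFit(
        family="logistic+linear",
        logit_res=logit_res,
        linear_res=linear_res,
        coef_names=names,
        time_center=time_center,
        zero_cells=zero_cells,
    )


# ---------------------------------------------------------------------------
# adjusted means
# ---------------------------------------------------------------------------


def _trunc_mean(mu, family, k=None):
    if family == "truncNB":
        p0 = np.exp(k * (np.log(k) - np.log(k + mu)))
        return mu / (1.0 - p0)
    if family == "truncPoisson":
        return mu / (-np.expm1(-mu))
    return mu


def _two_part_cell_mean(fit: TwoPartFit, x: np.ndarray, theta1, theta2) -> float:
    b1 = fit.part1.coef_from_theta(theta1)
    b2 = fit.part2.coef_from_theta(theta2)
    p = expit(float(x @ b1))
    mu = float(np.exp(np.clip(x @ b2, -_ETA_MAX, _ETA_MAX)))
    fam2 = "truncNB" if fit.family == "two_part_truncNB" else "truncPoisson"
    k = fit.part2.dispersion_from_theta(theta2)
    return p * float(_trunc_mean(mu, fam2, k))


def _numeric_grad(f, theta, h=1e-6):
    g = np.zeros_like(theta)
    for j in range(len(theta)):
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        g[j] = (f(tp) - f(tm)) / (2 * h)
    return g


@_quiet
def _predict_cell(fit, x: np.ndarray) -> tuple[float, float]:
    """Conditional adjusted mean and delta-method SE for one cell row."""
    if isinstance(fit, TwoPartFit):
        t1, t2 = fit.part1.theta, fit.part2.theta
        mean = _two_part_cell_mean(fit, x, t1, t2)
        g1 = _numeric_grad(lambda t: _two_part_cell_mean(fit, x, t, t2), t1)
        g2 = _numeric_grad(lambda t: _two_part_cell_mean(fit, x, t1, t), t2)
        var = float(g1 @ fit.part1.cov @ g1 + g2 @ fit.part2.cov @ g2)
        return mean, float(np.sqrt(max(var, 0.0)))
    if isinstance(fit, OnePartFit):
        t = fit.part.theta

        def f(theta):
            b = fit.part.coef_from_theta(theta)
            return float(np.exp(np.clip(x @ b, -_ETA_MAX, _ETA_MAX)))

        mean = f(t)
        g = _numeric_grad(f, t)
        var = float(g @ fit.part.cov @ g)
        return mean, float(np.sqrt(max(var, 0.0)))
    if isinstance(fit, FallbackFit):
        p = float(fit.logit_res.predict(x[None, :])[0])
        if fit.linear_res is None:
            return 0.0, 0.0
        days = max(float(fit.linear_res.predict(x[None, :])[0]), 0.0)
        mean = p * days
        # delta method; the two regressions are treated as independent
        pe = p * (1 - p)
        var_eta = float(x @ fit.logit_res.cov_params() @ x)
        var_days = float(x @ fit.linear_res.cov_params() @ x)
        var = (days * pe) ** 2 * var_eta + p**2 * var_days
        return mean, float(np.sqrt(max(var, 0.0)))
    raise TypeError(f"unsupported fit type {type(fit)!r}")


def adjusted_means(fit, category: str, records: pd.DataFrame) -> pd.DataFrame:
    """Model-predicted mean resource use per (subgroup, arm) cell.

    Predictions are conditional: centred time fixed at 0 and the centre
    random effect at 0. Cells absent from the data (or with no use at
    all under the fallback) are emitted as fixed zeros. All 9 x 2 cells
    are always present in the output.
    """
    rows = []
    for b, d in SUBGROUPS:
        for arm in ARMS:
            mask = (
                (records["plgf_category"] == b)
                & (records["diagnosis"] == d)
                & (records["arm"] == arm)
            )
            absent = not bool(mask.any())
            zero_cell = isinstance(fit, FallbackFit) and (b, d, arm) in fit.zero_cells
            if absent or zero_cell:
                if absent:
                    logger.warning(
                        "subgroup %s x %s absent from %s arm; fixed at 0",
                        b, d, arm,
                    )
                mean, se, tag = 0.0, 0.0, "fixed"
            else:
                x = cell_covariates(fit.coef_names, b, d, arm)
                mean, se = _predict_cell(fit, x)
                tag = "fixed" if se == 0.0 else "normal_truncated0"
            rows.append(
                {
                    "category": category,
                    "plgf_category": b,
                    "diagnosis": d,
                    "arm": arm,
                    "mean": mean,
                    "se": se,
                    "distribution_tag": tag,
                }
            )
    return pd.DataFrame(rows)


def fit_all_categories(
    records: pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    n_quad: int = 7,
) -> tuple[pd.DataFrame, dict]:
    """Run model selection (with fallback escalation) for every resource
    category and stack the adjusted-mean grids."""
    frames = []
    info: dict[str, dict] = {}
    for category in CATEGORIES:
        try:
            spec, fit = select_model(records, category, candidates, n_quad)
            info[category] = {
                "family": spec.family,
                "aic": fit.aic,
                "fallback": False,
            }
        except NoConvergedModelError:
            fit = fit_fallback(records, category)
            info[category] = {"family": fit.family, "aic": None, "fallback": True}
            logger.info("category %s fell back to logistic+linear", category)
        frames.append(adjusted_means(fit, category, records))
    return pd.concat(frames, ignore_index=True), info


# ---------------------------------------------------------------------------
# delivery cost (reported separately; excluded from the Monte Carlo totals)
# ---------------------------------------------------------------------------


@_quiet
def fit_delivery_cost(records: pd.DataFrame, unit_costs) -> pd.DataFrame:
    """Per-arm mean delivery cost with Wald 95% CI from a gamma-log GLMM
    (arm + linear time + centre random intercept)."""
    costs = records["delivery_mode"].map(unit_costs.delivery_costs)
    if costs.isna().any():
        missing = sorted(set(records["delivery_mode"][costs.isna()]))
        raise ValueError(f"no delivery cost for modes: {missing}")
    y = costs.to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("delivery costs must be positive (gamma support)")
    if np.ptp(y) == 0.0:
        rows = [
            {"arm": arm, "mean": float(y[0]), "lo": float(y[0]), "hi": float(y[0])}
            for arm in ARMS
        ]
        return pd.DataFrame(rows)
    arm = (records["arm"].to_numpy() == "revealed").astype(float)
    time = records["step"].to_numpy(dtype=float)
    time = time - time.mean()
    X = np.column_stack([np.ones(len(y)), arm, time])
    fit = _fit_mixed(
        y, X, records["cluster"].to_numpy(), "gamma_log", coef_names=["const", "arm", "time"]
    )
    rows = []
    for arm_name in ARMS:
        a = 1.0 if arm_name == "revealed" else 0.0
        x = np.array([1.0, a, 0.0])
        nfree = int((~fit.pinned).sum())
        xe = np.zeros(len(fit.theta))
        xe[:nfree] = x[~fit.pinned]
        eta = float(x @ fit.coef)
        se = float(np.sqrt(max(xe @ fit.cov @ xe, 0.0)))
        rows.append(
            {
                "arm": arm_name,
                "mean": float(np.exp(eta)),
                "lo": float(np.exp(eta - 1.959964 * se)),
                "hi": float(np.exp(eta + 1.959964 * se)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MEANS_COLUMNS = (
    "category",
    "plgf_category",
    "diagnosis",
    "arm",
    "mean",
    "se",
    "distribution_tag",
)


def write_adjusted_means(df: pd.DataFrame, path) -> None:
    df[list(_MEANS_COLUMNS)].to_csv(path, index=False)


def read_adjusted_means(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_MEANS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"adjusted-means file missing columns: {sorted(missing)}")
    return df
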