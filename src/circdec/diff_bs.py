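"""Differential back-splicing: psi quantification and hierarchical testing.

The percent back-spliced in of a locus in one sample is

    psi = (CJC/Ic) / (LJC/Il + CJC/Ic)

with effective lengths Ic, Il correcting for the different number of read
start positions that can span a circular vs. linear junction. For large
circles (e >= 2L) this reduces to CJC/(LJC/2 + CJC).

Differential testing follows the hierarchical framework used for replicate
alternative-splicing analysis: within replicate k the circular junction
count is Binomial(CJC_k + LJC_k, p(psi_k)) with p the expected circular
read fraction, and logit(psi_k) is Normal(logit(mu_g), sigma_g^2) across
replicates of group g (bivariate normal with correlation rho across members
of a pair in paired mode). The null constrains |mu1 - mu2| to a user
threshold delta; the likelihood-ratio statistic is referred to chi-square
with 1 df. Replicate integrals use fixed-order Gauss-Hermite quadrature on
the logit scale, recentred at each integrand's mode for accuracy at deep
counts.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, logsumexp
from scipy.stats import chi2, fisher_exact

from .types import (
    CjcTable,
    ConfigError,
    DecTest,
    EffectiveLengths,
    GroupDesign,
    LjcTable,
    ModelFit,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------- constants

GH_ORDER = 32  # Gauss-Hermite quadrature order (logit scale)
SIGMA_MIN = 1e-4  # lower bound avoiding degenerate likelihood spikes
SIGMA_MAX = 5.0
RHO_MAX = 0.99
MU_EPS = 1e-6

_GH_T, _GH_W = np.polynomial.hermite.hermgauss(GH_ORDER)
_GH_LOGW = np.log(_GH_W)

DEFAULT_DELTA = 0.05
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_MEAN_CJC = 2.0


# ---------------------------------------------------------------- psi algebra


def compute_psi(cjc: float, ljc: float, lengths: EffectiveLengths) -> float:
    """Percent back-spliced in; NaN when cjc = ljc = 0."""
    if cjc < 0 or ljc < 0:
        raise ValueError("negative junction count")
    if cjc == 0 and ljc == 0:
        return float("nan")
    c = cjc / lengths.Ic
    return c / (ljc / lengths.Il + c)


def binomial_rate(psi: float, lengths: EffectiveLengths) -> float:
    """Expected circular fraction of junction reads at back-splice level psi.

    Inverts the psi formula: a locus with ratio psi yields circular junction
    reads with probability p = psi*Ic / (psi*Ic + (1-psi)*Il) per junction
    read, so compute_psi(p*N, (1-p)*N) == psi.
    """
    num = psi * lengths.Ic
    return num / (num + (1.0 - psi) * lengths.Il)


# ------------------------------------------------------- replicate likelihood


def _log_expit(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _lse(arr: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp (last axis) without scipy call overhead."""
    mx = arr.max(axis=-1, keepdims=True)
    return (mx + np.log(np.exp(arr - mx).sum(axis=-1, keepdims=True)))[..., 0]


def _replicate_nodes(
    c: np.ndarray, n: np.ndarray, a: float, m: float, sigma: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Mode-recentred quadrature nodes and the integrand log-density.

    ``a = log(Ic/Il)`` is the length offset: the circular read fraction is
    expit(x + a) when logit(psi) = x. The integrand mode solves a 1-D
    logistic-Gaussian problem by Newton iteration; the curvature there sets
    the node scale. Returns (nodes, h, log_i_core, sigma) where log_i_core
    lacks the binomial coefficient.
    """
    sigma = max(sigma, SIGMA_MIN)
    inv_v = 1.0 / (sigma * sigma)
    x = np.full(c.shape, m, dtype=float)
    for _ in range(40):
        p = expit(x + a)
        grad = c - n * p - (x - m) * inv_v
        hess = -n * p * (1.0 - p) - inv_v
        step = grad / hess
        np.clip(step, -4.0, 4.0, out=step)
        x -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(x + a)
    hess = -n * p * (1.0 - p) - inv_v
    tau = 1.0 / np.sqrt(-hess)
    nodes = x[:, None] + math.sqrt(2.0) * tau[:, None] * _GH_T[None, :]
    z = nodes + a
    h = (
        c[:, None] * _log_expit(z)
        + (n - c)[:, None] * _log_expit(-z)
        - 0.5 * math.log(2.0 * math.pi)
        - math.log(sigma)
        - 0.5 * (nodes - m) ** 2 * inv_v
    )
    log_i = 0.5 * math.log(2.0) + np.log(tau) + _lse(_GH_LOGW + _GH_T**2 + h)
    return nodes, h, log_i, sigma


def _replicate_loglik(
    c: np.ndarray, n: np.ndarray, a: float, m: float, sigma: float
) -> np.ndarray:
    """Marginal log-likelihood of each informative replicate."""
    _, _, log_i, _ = _replicate_nodes(c, n, a, m, sigma)
    return log_i + gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1)


def _replicate_loglik_grad(
    c: np.ndarray, n: np.ndarray, a: float, m: float, sigma: float
) -> tuple[float, float, float]:
    """(sum loglik, d/dm, d/d log sigma) for one group's replicates.

    The gradient of each marginal log-likelihood is the posterior
    expectation of the prior score, computed from the same quadrature nodes:
    d/dm = E[(x - m)/sigma^2], d/dlog sigma = E[(x - m)^2/sigma^2 - 1].
    """
    nodes, h, log_i, sigma = _replicate_nodes(c, n, a, m, sigma)
    lw = _GH_LOGW + _GH_T**2 + h
    w = np.exp(lw - lw.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    d = (nodes - m) / sigma
    g_m = float((w * d).sum() / sigma)
    g_ls = float((w * (d * d - 1.0)).sum())
    const = gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1)
    return float((log_i + const).sum()), g_m, g_ls


def loglik_group(
    counts: Sequence[tuple[int, int]],
    lengths: EffectiveLengths,
    mu: float,
    sigma: float,
) -> float:
    """Marginal log-likelihood of one group's replicates at (mu, sigma).

    Replicates with cjc + ljc = 0 carry no information and are skipped;
    at least one informative replicate is required.
    """
    c = np.array([cjc for cjc, ljc in counts], dtype=float)
    n = np.array([cjc + ljc for cjc, ljc in counts], dtype=float)
    keep = n > 0
    if not keep.any():
        raise ValueError("no informative replicate (all cjc + ljc = 0)")
    a = math.log(lengths.Ic / lengths.Il)
    m = float(logit(np.clip(mu, MU_EPS, 1.0 - MU_EPS)))
    return float(_replicate_loglik(c[keep], n[keep], a, m, sigma).sum())


# --------------------------------------------------------- unpaired fitting


def _moment_init(c: np.ndarray, n: np.ndarray, a: float) -> float:
    """Logit-scale location init from the pooled circular read fraction."""
    p_hat = np.clip((c.sum() + 0.5) / (n.sum() + 1.0), 1e-4, 1.0 - 1e-4)
    return float(logit(p_hat)) - a


def _fit_one_group(c: np.ndarray, n: np.ndarray, a: float) -> tuple[float, float, float, bool]:
    """Maximize the group marginal likelihood over (m, log sigma)."""

    def nll(theta: np.ndarray) -> tuple[float, np.ndarray]:
        m, log_s = theta
        ll, g_m, g_ls = _replicate_loglik_grad(c, n, a, m, math.exp(log_s))
        return -ll, -np.array([g_m, g_ls])

    m0 = _moment_init(c, n, a)
    best = None
    ok = False
    for log_s0 in (math.log(0.1), math.log(0.7)):
        res = minimize(
            nll,
            np.array([m0, log_s0]),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-13.0, 13.0), (math.log(SIGMA_MIN), math.log(SIGMA_MAX))],
        )
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or bool(res.success)
    m, log_s = best.x
    return float(m), math.exp(float(log_s)), -float(best.fun), ok


def _fit_constrained_unpaired(
    c1, n1, c2, n2, a: float, delta: float, sign: float, m_init: float
) -> tuple[float, float, float, float, float, bool]:
    """Boundary fit with mu1 - mu2 = sign * delta on the natural scale."""

    def tied(m1: float) -> tuple[float, float]:
        mu1 = float(expit(m1))
        mu2 = float(np.clip(mu1 - sign * delta, MU_EPS, 1.0 - MU_EPS))
        return mu1, mu2

    def nll(theta: np.ndarray) -> tuple[float, np.ndarray]:
        m1, ls1, ls2 = theta
        mu1, mu2 = tied(m1)
        ll1, g1m, g1s = _replicate_loglik_grad(c1, n1, a, float(logit(mu1)), math.exp(ls1))
        ll2, g2m, g2s = _replicate_loglik_grad(c2, n2, a, float(logit(mu2)), math.exp(ls2))
        # chain rule through the natural-scale tie mu2 = mu1 - sign*delta
        dm2_dm1 = 0.0
        if MU_EPS < mu2 < 1.0 - MU_EPS:
            dm2_dm1 = mu1 * (1.0 - mu1) / (mu2 * (1.0 - mu2))
        g_m1 = g1m + g2m * dm2_dm1
        return -(ll1 + ll2), -np.array([g_m1, g1s, g2s])

    best = None
    ok = False
    sb = (math.log(SIGMA_MIN), math.log(SIGMA_MAX))
    for log_s0 in (math.log(0.1), math.log(0.7)):
        res = minimize(
            nll,
            np.array([m_init, log_s0, log_s0]),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-13.0, 13.0), sb, sb],
        )
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or bool(res.success)
    m1, ls1, ls2 = best.x
    mu1, mu2 = tied(float(m1))
    return mu1, mu2, math.exp(float(ls1)), math.exp(float(ls2)), -float(best.fun), ok


def lrt_unpaired(
    group1: Sequence[tuple[int, int]],
    group2: Sequence[tuple[int, int]],
    lengths: EffectiveLengths,
    delta_threshold: float = DEFAULT_DELTA,
) -> tuple[ModelFit, float, float]:
    """Likelihood-ratio test of |mu1 - mu2| > delta, independent replicates.

    The unconstrained likelihood separates by group; the constrained optimum
    sits on the boundary |mu1 - mu2| = delta whenever the unconstrained fit
    violates the constraint. Returns (fit, llr, pvalue) with llr floored at
    0 and the p-value from chi-square with 1 df.
    """
    if not (0.0 <= delta_threshold <= 1.0):
        raise ConfigError("delta_threshold must be in [0, 1]")
    a = math.log(lengths.Ic / lengths.Il)
    arrs = []
    for grp in (group1, group2):
        c = np.array([x[0] for x in grp], dtype=float)
        n = np.array([x[0] + x[1] for x in grp], dtype=float)
        keep = n > 0
        if not keep.any():
            raise ValueError("group without informative replicates")
        arrs.append((c[keep], n[keep]))
    (c1, n1), (c2, n2) = arrs

    try:
        m1, s1, ll1, ok1 = _fit_one_group(c1, n1, a)
        m2, s2, ll2, ok2 = _fit_one_group(c2, n2, a)
        mu1, mu2 = float(expit(m1)), float(expit(m2))
        ll_u = ll1 + ll2
        converged = ok1 and ok2

        if abs(mu1 - mu2) <= delta_threshold + 1e-12:
            fit = ModelFit(mu1, mu2, s1, s2, None, ll_u, converged)
            return fit, 0.0, 1.0

        sign = 1.0 if mu1 > mu2 else -1.0
        mid = float(logit(np.clip((mu1 + mu2) / 2.0, MU_EPS, 1.0 - MU_EPS)))
        *_, ll_c, ok_c = _fit_constrained_unpaired(
            c1, n1, c2, n2, a, delta_threshold, sign, mid
        )
        llr = max(0.0, 2.0 * (ll_u - ll_c))
        pvalue = float(chi2.sf(llr, df=1))
        fit = ModelFit(mu1, mu2, s1, s2, None, ll_u, converged and ok_c)
        return fit, llr, pvalue
    except Exception:  # pragma: no cover - defensive: never abort a run
        logger.exception("unpaired LRT failed; reporting pvalue 1")
        return ModelFit(np.nan, np.nan, np.nan, np.nan, None, np.nan, False), 0.0, 1.0


# ----------------------------------------------------------- paired fitting


def _pair_loglik(
    c1, n1, c2, n2, a: float, m1: float, m2: float, s1: float, s2: float, rho: float,
    with_grad: bool = False,
):
    """Joint log-likelihood of fully informative pairs (vectorized).

    The pair integral over (x1, x2) ~ BVN is evaluated by mode-recentred
    tensor-product Gauss-Hermite quadrature: a 2-D Newton solve finds the
    integrand mode, the negative Hessian's inverse Cholesky factor scales
    the node grid. With ``with_grad`` the posterior-expected prior score is
    returned as the gradient wrt (m1, m2, log s1, log s2, rho).
    """
    s1 = max(s1, SIGMA_MIN)
    s2 = max(s2, SIGMA_MIN)
    rho = float(np.clip(rho, -RHO_MAX, RHO_MAX))
    det = (1.0 - rho * rho) * s1 * s1 * s2 * s2
    # precision matrix
    q11 = s2 * s2 / det
    q22 = s1 * s1 / det
    q12 = -rho * s1 * s2 / det

    x1 = np.full(c1.shape, m1, dtype=float)
    x2 = np.full(c2.shape, m2, dtype=float)
    for _ in range(60):
        p1 = expit(x1 + a)
        p2 = expit(x2 + a)
        d1, d2 = x1 - m1, x2 - m2
        g1 = c1 - n1 * p1 - (q11 * d1 + q12 * d2)
        g2 = c2 - n2 * p2 - (q12 * d1 + q22 * d2)
        h11 = -n1 * p1 * (1.0 - p1) - q11
        h22 = -n2 * p2 * (1.0 - p2) - q22
        h12 = -q12
        deth = h11 * h22 - h12 * h12
        st1 = (h22 * g1 - h12 * g2) / deth
        st2 = (h11 * g2 - h12 * g1) / deth
        np.clip(st1, -4.0, 4.0, out=st1)
        np.clip(st2, -4.0, 4.0, out=st2)
        x1 -= st1
        x2 -= st2
        if max(np.max(np.abs(st1)), np.max(np.abs(st2))) < 1e-11:
            break

    p1 = expit(x1 + a)
    p2 = expit(x2 + a)
    h11 = n1 * p1 * (1.0 - p1) + q11  # negative Hessian (pos. definite)
    h22 = n2 * p2 * (1.0 - p2) + q22
    h12 = q12
    deth = h11 * h22 - h12 * h12
    # Cholesky of the inverse of the negative Hessian, per pair
    b11 = h22 / deth
    b12 = -h12 / deth
    b22 = h11 / deth
    cl11 = np.sqrt(b11)
    cl21 = b12 / cl11
    cl22 = np.sqrt(np.maximum(b22 - cl21 * cl21, 1e-300))

    t1 = np.repeat(_GH_T, GH_ORDER)
    t2 = np.tile(_GH_T, GH_ORDER)
    logw = np.repeat(_GH_LOGW, GH_ORDER) + np.tile(_GH_LOGW, GH_ORDER) + t1**2 + t2**2
    sqrt2 = math.sqrt(2.0)
    y1 = x1[:, None] + sqrt2 * cl11[:, None] * t1[None, :]
    y2 = x2[:, None] + sqrt2 * (cl21[:, None] * t1[None, :] + cl22[:, None] * t2[None, :])

    z1 = y1 + a
    z2 = y2 + a
    d1 = y1 - m1
    d2 = y2 - m2
    quad = q11 * d1 * d1 + 2.0 * q12 * d1 * d2 + q22 * d2 * d2
    h = (
        c1[:, None] * _log_expit(z1)
        + (n1 - c1)[:, None] * _log_expit(-z1)
        + c2[:, None] * _log_expit(z2)
        + (n2 - c2)[:, None] * _log_expit(-z2)
        - math.log(2.0 * math.pi)
        - 0.5 * math.log(det)
        - 0.5 * quad
    )
    lwh = logw[None, :] + h
    log_i = math.log(2.0) + np.log(cl11 * cl22) + _lse(lwh)
    const = (
        gammaln(n1 + 1) - gammaln(c1 + 1) - gammaln(n1 - c1 + 1)
        + gammaln(n2 + 1) - gammaln(c2 + 1) - gammaln(n2 - c2 + 1)
    )
    total = float((log_i + const).sum())
    if not with_grad:
        return total
    w = np.exp(lwh - lwh.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    zz1 = d1 / s1
    zz2 = d2 / s2
    omr = 1.0 - rho * rho
    g_m1 = float((w * (q11 * d1 + q12 * d2)).sum())
    g_m2 = float((w * (q12 * d1 + q22 * d2)).sum())
    g_ls1 = float((w * ((zz1 * zz1 - rho * zz1 * zz2) / omr - 1.0)).sum())
    g_ls2 = float((w * ((zz2 * zz2 - rho * zz1 * zz2) / omr - 1.0)).sum())
    g_rho = float(
        (
            w
            * (
                rho / omr
                + (zz1 * zz2 * (1.0 + rho * rho) - rho * (zz1 * zz1 + zz2 * zz2))
                / (omr * omr)
            )
        ).sum()
    )
    return total, np.array([g_m1, g_m2, g_ls1, g_ls2, g_rho])


def _paired_loglik(
    pairs1, pairs2, a: float, m1: float, m2: float, s1: float, s2: float, rho: float,
    with_grad: bool = False,
):
    """Full paired log-likelihood, marginalizing half-informative pairs.

    With ``with_grad`` also returns the gradient wrt
    (m1, m2, log s1, log s2, rho).
    """
    c1, n1, c2, n2 = pairs1[0], pairs1[1], pairs2[0], pairs2[1]
    both = (n1 > 0) & (n2 > 0)
    only1 = (n1 > 0) & (n2 == 0)
    only2 = (n1 == 0) & (n2 > 0)
    ll = 0.0
    grad = np.zeros(5)
    if both.any():
        res = _pair_loglik(
            c1[both], n1[both], c2[both], n2[both], a, m1, m2, s1, s2, rho,
            with_grad=with_grad,
        )
        if with_grad:
            ll += res[0]
            grad += res[1]
        else:
            ll += res
    if only1.any():
        sub_ll, g_m, g_ls = _replicate_loglik_grad(c1[only1], n1[only1], a, m1, s1)
        ll += sub_ll
        grad[0] += g_m
        grad[2] += g_ls
    if only2.any():
        sub_ll, g_m, g_ls = _replicate_loglik_grad(c2[only2], n2[only2], a, m2, s2)
        ll += sub_ll
        grad[1] += g_m
        grad[3] += g_ls
    if with_grad:
        return ll, grad
    return ll


def lrt_paired(
    group1: Sequence[tuple[int, int]],
    group2: Sequence[tuple[int, int]],
    lengths: EffectiveLengths,
    delta_threshold: float = DEFAULT_DELTA,
) -> tuple[ModelFit, float, float]:
    """Paired likelihood-ratio test: pair k's (logit psi_1k, logit psi_2k)
    is bivariate normal with correlation rho shared across pairs.

    Same constraint, statistic and chi-square(1) reference as the unpaired
    test; rho is estimated jointly and pinned to (-0.99, 0.99).
    """
    if len(group1) != len(group2):
        raise ConfigError("paired test requires equal-length replicate lists")
    if not (0.0 <= delta_threshold <= 1.0):
        raise ConfigError("delta_threshold must be in [0, 1]")
    a = math.log(lengths.Ic / lengths.Il)
    c1 = np.array([x[0] for x in group1], dtype=float)
    n1 = np.array([x[0] + x[1] for x in group1], dtype=float)
    c2 = np.array([x[0] for x in group2], dtype=float)
    n2 = np.array([x[0] + x[1] for x in group2], dtype=float)
    if not (n1 > 0).any() or not (n2 > 0).any():
        raise ValueError("group without informative replicates")
    pairs1, pairs2 = (c1, n1), (c2, n2)

    try:
        # moment/fallback inits from per-group independent fits
        g1m, g1s, _, _ = _fit_one_group(c1[n1 > 0], n1[n1 > 0], a)
        g2m, g2s, _, _ = _fit_one_group(c2[n2 > 0], n2[n2 > 0], a)
        both = (n1 > 0) & (n2 > 0)
        rho0 = 0.0
        if both.sum() >= 3:
            l1 = logit(np.clip((c1[both] + 0.5) / (n1[both] + 1.0), 1e-4, 1 - 1e-4))
            l2 = logit(np.clip((c2[both] + 0.5) / (n2[both] + 1.0), 1e-4, 1 - 1e-4))
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(l1, l2)[0, 1]
            if np.isfinite(r):
                rho0 = float(np.clip(r, -0.9, 0.9))

        sb = (math.log(SIGMA_MIN), math.log(SIGMA_MAX))
        zb = math.atanh(RHO_MAX)

        def nll_u(theta: np.ndarray) -> tuple[float, np.ndarray]:
            m1, m2, ls1, ls2, z = theta
            rho = math.tanh(z)
            ll, g = _paired_loglik(
                pairs1, pairs2, a, m1, m2, math.exp(ls1), math.exp(ls2), rho,
                with_grad=True,
            )
            g = g.copy()
            g[4] *= 1.0 - rho * rho  # d rho / d z
            return -ll, -g

        best = None
        ok = False
        for z0 in (math.atanh(rho0), 0.0):
            res = minimize(
                nll_u,
                np.array([g1m, g2m, math.log(max(g1s, 0.05)), math.log(max(g2s, 0.05)), z0]),
                jac=True,
                method="L-BFGS-B",
                bounds=[(-13, 13), (-13, 13), sb, sb, (-zb, zb)],
            )
            if best is None or res.fun < best.fun:
                best = res
            ok = ok or bool(res.success)
        m1_hat, m2_hat, ls1, ls2, z = best.x
        mu1, mu2 = float(expit(m1_hat)), float(expit(m2_hat))
        s1_hat, s2_hat = math.exp(float(ls1)), math.exp(float(ls2))
        rho_hat = math.tanh(float(z))
        ll_u = -float(best.fun)
        fit = ModelFit(mu1, mu2, s1_hat, s2_hat, rho_hat, ll_u, ok)

        if abs(mu1 - mu2) <= delta_threshold + 1e-12:
            return fit, 0.0, 1.0

        sign = 1.0 if mu1 > mu2 else -1.0

        def nll_c(theta: np.ndarray) -> tuple[float, np.ndarray]:
            mm1, ls1, ls2, z = theta
            rho = math.tanh(z)
            u1 = float(expit(mm1))
            u2 = float(np.clip(u1 - sign * delta_threshold, MU_EPS, 1.0 - MU_EPS))
            ll, g = _paired_loglik(
                pairs1,
                pairs2,
                a,
                float(logit(u1)),
                float(logit(u2)),
                math.exp(ls1),
                math.exp(ls2),
                rho,
                with_grad=True,
            )
            dm2_dm1 = 0.0
            if MU_EPS < u2 < 1.0 - MU_EPS:
                dm2_dm1 = u1 * (1.0 - u1) / (u2 * (1.0 - u2))
            gv = np.array(
                [g[0] + g[1] * dm2_dm1, g[2], g[3], g[4] * (1.0 - rho * rho)]
            )
            return -ll, -gv

        mid = float(logit(np.clip((mu1 + mu2) / 2.0, MU_EPS, 1.0 - MU_EPS)))
        res_c = minimize(
            nll_c,
            np.array([mid, ls1, ls2, z]),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-13, 13), sb, sb, (-zb, zb)],
        )
        ll_c = -float(res_c.fun)
        llr = max(0.0, 2.0 * (ll_u - ll_c))
        pvalue = float(chi2.sf(llr, df=1))
        fit.converged = fit.converged and bool(res_c.success)
        return fit, llr, pvalue
    except Exception:  # pragma: no cover - defensive
        logger.exception("paired LRT failed; reporting pvalue 1")
        return ModelFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False), 0.0, 1.0


# ---------------------------------------------------------------- auxiliary


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def fisher_baseline(
    group1: Sequence[tuple[int, int]], group2: Sequence[tuple[int, int]]
) -> float:
    """Two-sided Fisher's exact test on pooled raw junction counts.

    The 2x2 table is [[sum CJC1, sum LJC1], [sum CJC2, sum LJC2]]; the
    baseline ignores replicate structure and effective lengths.
    """
    if not group1 or not group2:
        raise ValueError("both groups need counts")
    table = np.array(
        [
            [sum(c for c, _ in group1), sum(l for _, l in group1)],
            [sum(c for c, _ in group2), sum(l for _, l in group2)],
        ],
        dtype=np.int64,
    )
    if table.sum() == 0:
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


# ------------------------------------------------------------- orchestration


def run_dec(
    cjc: CjcTable,
    ljc: LjcTable,
    lengths: Mapping[str, EffectiveLengths] | Sequence[EffectiveLengths],
    design: GroupDesign,
    delta_threshold: float = DEFAULT_DELTA,
    alpha: float = DEFAULT_ALPHA,
    min_mean_cjc: float = DEFAULT_MIN_MEAN_CJC,
) -> list[DecTest]:
    """Full differential back-splicing analysis of a two-group design.

    Applies the mean-CJC filter, computes per-sample psi, runs the paired or
    unpaired LRT per locus, adjusts p-values by Benjamini-Hochberg, and
    flags loci with fdr < alpha and |delta psi| > delta_threshold as DECs.
    Loci lacking an informative replicate in either group are dropped.
    """
    from .merge import filter_mean_cjc

    if not isinstance(lengths, Mapping):
        if len(lengths) != len(cjc.loci):
            raise ValueError("lengths sequence does not align with cjc loci")
        lengths = {loc.locus_id: el for loc, el in zip(cjc.loci, lengths)}

    cjc_ids = set(cjc.locus_ids)
    ljc_ids = set(ljc.locus_ids)
    if cjc_ids != ljc_ids:
        diff = sorted(cjc_ids.symmetric_difference(ljc_ids))
        raise ValueError(f"cjc/ljc locus sets differ: {diff[:20]}")
    missing_len = sorted(cjc_ids - set(lengths))
    if missing_len:
        raise ValueError(f"loci without effective lengths: {missing_len[:20]}")

    cjc = filter_mean_cjc(cjc, min_mean_cjc)
    ljc_frame_up = {lid: i for i, lid in enumerate(ljc.locus_ids)}
    col = {s: j for j, s in enumerate(cjc.samples)}
    lcol = {s: j for j, s in enumerate(ljc.samples)}
    missing_samples = [s for s in design.samples if s not in col or s not in lcol]
    if missing_samples:
        raise ValueError(f"design samples missing from tables: {missing_samples}")

    g1_idx = [col[s] for s in design.group1]
    g2_idx = [col[s] for s in design.group2]
    lg1 = [lcol[s] for s in design.group1]
    lg2 = [lcol[s] for s in design.group2]

    tests: list[DecTest] = []
    ljc_total = ljc.ljc
    for i, locus in enumerate(cjc.loci):
        lid = locus.locus_id
        li = ljc_frame_up[lid]
        el = lengths[lid]
        c_row = cjc.cjc[i]
        l_row = ljc_total[li]
        g1 = [(int(c_row[j]), int(l_row[k])) for j, k in zip(g1_idx, lg1)]
        g2 = [(int(c_row[j]), int(l_row[k])) for j, k in zip(g2_idx, lg2)]
        psi_all = [
            compute_psi(int(c_row[col[s]]), int(l_row[lcol[s]]), el)
            for s in design.samples
        ]
        psi1 = [p for (c, l), p in zip(g1, psi_all[: len(g1)]) if c + l > 0]
        psi2 = [p for (c, l), p in zip(g2, psi_all[len(g1):]) if c + l > 0]
        if not psi1 or not psi2:
            logger.warning("%s: no informative replicate in one group; skipped", lid)
            continue
        psi1_avg = float(np.mean(psi1))
        psi2_avg = float(np.mean(psi2))
        test_fn = lrt_paired if design.paired else lrt_unpaired
        fit, llr, pvalue = test_fn(g1, g2, el, delta_threshold)
        tests.append(
            DecTest(
                locus_id=lid,
                psi_per_sample=psi_all,
                psi1_avg=psi1_avg,
                psi2_avg=psi2_avg,
                delta_psi=psi1_avg - psi2_avg,
                llr=llr,
                pvalue=pvalue,
                fit=fit,
            )
        )

    if tests:
        fdrs = bh_fdr([t.pvalue for t in tests])
        for t, f in zip(tests, fdrs):
            t.fdr = float(f)
            t.is_dec = bool(t.fdr < alpha and abs(t.delta_psi) > delta_threshold)
    return tests


def results_frame(tests: Sequence[DecTest]):
    """Results as a DataFrame matching the TSV output layout."""
    import pandas as pd

    rows = []
    for t in tests:
        fit = t.fit or ModelFit(np.nan, np.nan, np.nan, np.nan, None, np.nan, False)
        rows.append(
            {
                "locus_id": t.locus_id,
                "psi_per_sample": ",".join(
                    "NA" if np.isnan(p) else f"{p:.6g}" for p in t.psi_per_sample
                ),
                "psi1_avg": t.psi1_avg,
                "psi2_avg": t.psi2_avg,
                "delta_psi": t.delta_psi,
                "llr": t.llr,
                "pvalue": t.pvalue,
                "fdr": t.fdr,
                "is_dec": t.is_dec,
                "mu1": fit.mu1,
                "mu2": fit.mu2,
                "sigma1": fit.sigma1,
                "sigma2": fit.sigma2,
                "rho": np.nan if fit.rho is None else fit.rho,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")
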