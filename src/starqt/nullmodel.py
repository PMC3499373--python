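"""Ascertainment-corrected null model and exchangeable residuals.

Extreme sampling on the primary trait y1 makes the secondary trait y2
non-exchangeable whenever (a) y1 and y2 are residually correlated and
(b) the gene region affects y1: selection enriches the tails for
primary-trait-raising genotypes, which drags the conditional mean of y2
along and creates spurious association.  The correction factorizes the
ascertained likelihood:

1. Fit the primary-trait mean and residual SD by maximum likelihood
   under two-sided truncation to the selection region, i.e. each
   selected individual contributes

       phi((y1 - mu)/sigma1) / sigma1
       -----------------------------------------------,
       Phi((lo - mu)/sigma1) + 1 - Phi((hi - mu)/sigma1)

   with mu = X1 @ gamma1 + beta_p * coding.  This recovers the
   *population* regression of y1 on the genotype coding despite the
   tail sampling.

2. Regress y2 by OLS on covariates and the primary-trait residual
   (y1 - mu_hat).  Because ascertainment acts only through y1, the
   conditional law of y2 given y1 is unaffected by selection, so this
   step needs no truncation correction.  The coefficient tau of
   (y1 - mu_hat) converges to rho * sigma2 / sigma1.

The residuals of step 2 are (approximately) i.i.d. under the null of no
gene/secondary-trait association and can be fed to any rare-variant
test with plain permutation inference.

Also provided: the large-sample bias of the naive analysis that ignores
ascertainment, by numerical integration over the truncated conditional
moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(z):
    return -0.5 * z * z - _LOG_SQRT_2PI

from .ascertain import SelectionRegion
from .simgen import GenotypeMatrix

__all__ = [
    "NullFit",
    "Residuals",
    "PrimaryFit",
    "fit_truncated_primary",
    "fit_conditional_secondary",
    "fit_null_joint",
    "compute_residuals",
    "naive_bias",
]


@dataclass
class PrimaryFit:
    """MLEs of the truncated primary-trait model."""

    gamma1: np.ndarray          # intercept + covariate coefficients
    beta_p_hat: float           # effect of the genotype coding (nan if dropped)
    sigma1_hat: float
    loglik: float
    converged: bool
    mu1: np.ndarray             # fitted (untruncated) means X1@gamma1 + beta_p*coding


@dataclass
class NullFit:
    gamma1: np.ndarray
    beta_p_hat: float
    sigma1_hat: float
    gamma2: np.ndarray
    tau_hat: float
    sigma_cond_hat: float
    converged: bool
    loglik: float


@dataclass
class Residuals:
    """Exchangeable secondary-trait residuals under the null."""

    e: np.ndarray
    sigma: float


def _design(y, X, coding):
    n = np.asarray(y).size
    cols = [np.ones(n)]
    names = ["intercept"]
    if X is not None:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        cols.append(Xa)
        names += [f"x{j}" for j in range(Xa.shape[1])]
    D = np.column_stack(cols)
    n_coding = 0
    if coding is not None:
        C = np.asarray(coding, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep = np.ptp(C, axis=0) > 0.0  # constant columns are non-identifiable
        C = C[:, keep]
        n_coding = C.shape[1]
        if n_coding:
            D = np.column_stack([D, C])
            names += [f"coding{j}" for j in range(n_coding)]
    return D, names, n_coding


# tiny L2 penalty on non-intercept coefficients: keeps the truncated MLE
# well-posed when rare-variant columns are nearly collinear (e.g. two
# singletons carried by the same individual)
_RIDGE = 1e-6


def _trunc_negloglik_and_grad(params, y, D, lo, hi):
    """Negative log-likelihood of the two-sided-truncated normal model and
    its gradient in (coefficients, log sigma).

    The truncation normalizer is evaluated with complementary-CDF log
    formulations (logcdf / logsf) to avoid cancellation at extreme cuts;
    an underflowing normalizer (a parameter point that makes the observed
    tails essentially impossible) is floored so the optimizer is pushed
    back smoothly instead of hitting NaNs.
    """
    b, log_s = params[:-1], params[-1]
    s = np.exp(log_s)
    mu = D @ b
    r = (y - mu) / s
    if not (np.isfinite(lo) or np.isfinite(hi)):
        # no truncation: plain normal likelihood (OLS-equivalent MLE)
        ll = _norm_logpdf(r) - log_s
        grad_b = -(D.T @ (r / s))
        grad_logs = -np.sum(r**2 - 1.0)
        nll = -np.sum(ll)
    else:
        a = (lo - mu) / s
        bb = (hi - mu) / s
        logZ = np.logaddexp(log_ndtr(a), log_ndtr(-bb))
        logZ = np.maximum(logZ, -700.0)
        ll = _norm_logpdf(r) - log_s - logZ
        pdf_a_over_Z = np.exp(np.minimum(_norm_logpdf(a) - logZ, 690.0))
        pdf_b_over_Z = np.exp(np.minimum(_norm_logpdf(bb) - logZ, 690.0))
        dll_dmu = r / s + (pdf_a_over_Z - pdf_b_over_Z) / s
        # d/dsigma, then chain to log sigma
        dll_ds = (r**2 - 1.0) / s - (bb * pdf_b_over_Z - a * pdf_a_over_Z) / s
        grad_b = -(D.T @ dll_dmu)
        grad_logs = -np.sum(dll_ds) * s
        nll = -np.sum(ll)
    pen = np.zeros_like(b)
    pen[1:] = b[1:]  # never penalize the intercept
    nll += _RIDGE * float(pen @ pen)
    grad_b += 2.0 * _RIDGE * pen
    return nll, np.concatenate([grad_b, [grad_logs]])


def fit_truncated_primary(
    y1, X1, primary_coding, region: SelectionRegion | None
) -> PrimaryFit:
    """Maximum-likelihood fit of y1 on (covariates, genotype coding) under
    two-sided truncation to the selection region.

    ``primary_coding`` may be a single scalar coding (vector) or an n x k
    matrix of per-variant codings, in which case ``beta_p_hat`` is a
    vector.  ``region=None`` means no truncation, in which case the MLEs
    coincide with OLS.  A constant (e.g. all-zero) coding column is
    non-identifiable and is dropped; a fully dropped coding reports
    ``beta_p_hat`` as nan.
    """
    y1 = np.asarray(y1, dtype=float)
    lo = -np.inf if region is None else region.lower_cut
    hi = np.inf if region is None else region.upper_cut
    if np.isfinite(lo) and np.isfinite(hi) and not ((y1 <= lo) | (y1 >= hi)).all():
        raise ValueError("some selected individuals' y1 lie outside the region")
    D, names, n_coding = _design(y1, X1, primary_coding)
    if primary_coding is not None and n_coding == 0:
        warnings.warn("genotype coding is constant; beta_p is non-identifiable and dropped")

    # OLS starting values on the selected sample
    coef0, *_ = np.linalg.lstsq(D, y1, rcond=None)
    resid0 = y1 - D @ coef0
    s0 = max(resid0.std(ddof=D.shape[1]), 1e-3)
    x0 = np.concatenate([coef0, [np.log(s0)]])

    res = optimize.minimize(
        _trunc_negloglik_and_grad, x0, args=(y1, D, lo, hi),
        jac=True, method="L-BFGS-B",
        options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 1000},
    )
    converged = bool(res.success)
    if not converged:
        # quasi-Newton restart from the best point so far; if that also
        # stalls, accept the point only when the gradient is numerically flat
        res2 = optimize.minimize(
            _trunc_negloglik_and_grad, res.x, args=(y1, D, lo, hi),
            jac=True, method="BFGS", options={"gtol": 1e-6, "maxiter": 500},
        )
        if res2.fun <= res.fun:
            res = res2
        grad_norm = float(np.max(np.abs(
            _trunc_negloglik_and_grad(res.x, y1, D, lo, hi)[1]
        )))
        converged = bool(res2.success) or grad_norm < 1e-4 * y1.size
    sigma1 = float(np.exp(res.x[-1]))
    if sigma1 < 1e-8:
        raise RuntimeError("sigma1 driven to boundary; truncated fit is degenerate")
    b = res.x[:-1]
    if n_coding > 0:
        gamma1 = b[:-n_coding]
        beta_p = float(b[-1]) if n_coding == 1 else b[-n_coding:]
    else:
        gamma1, beta_p = b, float("nan")
    mu1 = D @ b
    return PrimaryFit(
        gamma1=gamma1, beta_p_hat=beta_p, sigma1_hat=sigma1,
        loglik=-float(res.fun), converged=converged, mu1=mu1,
    )


def _joint_negloglik_and_grad(params, y1, y2, D1, D2, lo, hi, n_pen):
    """Negative log-likelihood of the re-parameterized joint null model

        f(y1 | G, A) * f(y2 | y1, G)

    with parameters (b, log sigma1, g2, tau, log sigma2|1), where
    mu1 = D1 @ b and the secondary conditional mean is
    D2 @ g2 + tau * (y1 - mu1).  The primary-trait coefficients are
    informed by both factors, which is what makes the residuals
    orthogonal to the nuisance directions (slightly conservative) rather
    than contaminated by estimation noise (anticonservative).
    """
    k1 = D1.shape[1]
    k2 = D2.shape[1]
    b = params[:k1]
    log_s1 = params[k1]
    g2 = params[k1 + 1:k1 + 1 + k2]
    tau = params[-2]
    log_s2 = params[-1]
    s1, s2 = np.exp(log_s1), np.exp(log_s2)

    mu1 = D1 @ b
    r1 = (y1 - mu1) / s1
    # primary factor (two-sided truncation)
    if not (np.isfinite(lo) or np.isfinite(hi)):
        ll1 = _norm_logpdf(r1) - log_s1
        dll1_dmu = r1 / s1
        dll1_dls1 = np.sum(r1**2 - 1.0)
    else:
        a = (lo - mu1) / s1
        bb = (hi - mu1) / s1
        logZ = np.maximum(np.logaddexp(log_ndtr(a), log_ndtr(-bb)), -700.0)
        ll1 = _norm_logpdf(r1) - log_s1 - logZ
        pdf_a = np.exp(np.minimum(_norm_logpdf(a) - logZ, 690.0))
        pdf_b = np.exp(np.minimum(_norm_logpdf(bb) - logZ, 690.0))
        dll1_dmu = r1 / s1 + (pdf_a - pdf_b) / s1
        dll1_dls1 = np.sum((r1**2 - 1.0) - (bb * pdf_b - a * pdf_a))
    # secondary factor (plain normal given y1)
    resid1 = y1 - mu1
    u = y2 - D2 @ g2 - tau * resid1
    r2 = u / s2
    ll2 = _norm_logpdf(r2) - log_s2
    dll2_dmu = -r2 * tau / s2          # through mu1 in the conditional mean
    grad_b = -(D1.T @ (dll1_dmu + dll2_dmu))
    grad_ls1 = -dll1_dls1
    grad_g2 = -(D2.T @ (r2 / s2))
    grad_tau = -np.sum(r2 * resid1) / s2
    grad_ls2 = -np.sum(r2**2 - 1.0)
    nll = -np.sum(ll1) - np.sum(ll2)
    # tiny ridge on the last n_pen primary coefficients (coding columns)
    if n_pen:
        pen = b[-n_pen:]
        nll += _RIDGE * float(pen @ pen)
        grad_b[-n_pen:] += 2.0 * _RIDGE * pen
    return nll, np.concatenate([grad_b, [grad_ls1], grad_g2, [grad_tau], [grad_ls2]])


def fit_null_joint(y1, y2, X1, X2, primary_coding, region: SelectionRegion | None) -> tuple[NullFit, Residuals]:
    """Joint MLE of the re-parameterized ascertained null model.

    Initialized from the factorized two-stage fit, then all parameters
    (gamma1, beta_p, sigma1, gamma2, tau, sigma2|1) are maximized
    together.  Returns the fit and the exchangeable residuals
    y2 - gamma2 - tau*(y1 - mu1).
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    lo = -np.inf if region is None else region.lower_cut
    hi = np.inf if region is None else region.upper_cut
    D1, _, n_coding = _design(y1, X1, primary_coding)
    D2, _, _ = _design(y2, X2, None)

    pf = fit_truncated_primary(y1, X1, primary_coding, region)
    fit0, _ = fit_conditional_secondary(y2, X2, y1, pf.mu1)
    b0 = np.concatenate([pf.gamma1, np.atleast_1d(pf.beta_p_hat)]) if n_coding else pf.gamma1
    x0 = np.concatenate([
        b0, [np.log(pf.sigma1_hat)],
        fit0.gamma2, [fit0.tau_hat], [np.log(fit0.sigma_cond_hat)],
    ])
    res = optimize.minimize(
        _joint_negloglik_and_grad, x0, args=(y1, y2, D1, D2, lo, hi, n_coding),
        jac=True, method="L-BFGS-B",
        options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 2000},
    )
    converged = bool(res.success)
    k1, k2 = D1.shape[1], D2.shape[1]
    b = res.x[:k1]
    sigma1 = float(np.exp(res.x[k1]))
    g2 = res.x[k1 + 1:k1 + 1 + k2]
    tau = float(res.x[-2])
    sigma2 = float(np.exp(res.x[-1]))
    if sigma1 < 1e-8 or sigma2 < 1e-8:
        raise RuntimeError("residual SD driven to boundary; joint null fit is degenerate")
    mu1 = D1 @ b
    e = y2 - D2 @ g2 - tau * (y1 - mu1)
    if n_coding > 0:
        gamma1 = b[:-n_coding]
        beta_p = float(b[-1]) if n_coding == 1 else b[-n_coding:]
    else:
        gamma1, beta_p = b, float("nan")
    fit = NullFit(
        gamma1=gamma1, beta_p_hat=beta_p, sigma1_hat=sigma1,
        gamma2=g2, tau_hat=tau, sigma_cond_hat=sigma2,
        converged=converged, loglik=-float(res.fun),
    )
    return fit, Residuals(e=e, sigma=sigma2)


def fit_conditional_secondary(y2, X2, y1, mu1_hat) -> tuple[NullFit, Residuals]:
    """OLS of y2 on intercept, covariates and the primary-trait residual.

    The coefficient of (y1 - mu1_hat) is tau_hat; the fit residuals are
    the exchangeable secondary-trait residuals.
    """
    y2 = np.asarray(y2, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    mu1_hat = np.asarray(mu1_hat, dtype=float)
    D, names, _ = _design(y2, X2, None)
    D = np.column_stack([D, y1 - mu1_hat])
    names.append("primary_residual")
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError(f"collinear secondary design (columns: {', '.join(names)})")
    coef, *_ = np.linalg.lstsq(D, y2, rcond=None)
    e = y2 - D @ coef
    dof = max(y2.size - D.shape[1], 1)
    sigma_cond = float(np.sqrt(e @ e / dof))
    fit = NullFit(
        gamma1=np.empty(0), beta_p_hat=float("nan"), sigma1_hat=float("nan"),
        gamma2=coef[:-1], tau_hat=float(coef[-1]), sigma_cond_hat=sigma_cond,
        converged=True, loglik=float("nan"),
    )
    return fit, Residuals(e=e, sigma=sigma_cond)


def compute_residuals(
    y1, y2, X1, X2, G: GenotypeMatrix | None, primary_coding, region: SelectionRegion | None,
    maf_cap: float = 0.05, mac_min: int = 10, method: str = "joint",
) -> tuple[NullFit, Residuals]:
    """Ascertainment-corrected null fit and exchangeable residuals.

    ``method='joint'`` (default) maximizes the full re-parameterized
    likelihood; ``method='two-stage'`` runs the factorized fits
    (truncated primary, then conditional secondary OLS).

    ``primary_coding`` is the genotype coding through which the gene may
    affect the primary trait: a scalar coding (e.g. the burden coding the
    downstream test uses) or an n x k per-variant matrix.  If None, a
    hybrid default is built from ``G``: every polymorphic site with
    MAF <= ``maf_cap`` and at least ``mac_min`` minor alleles enters the
    truncated fit as its own column (so per-site primary-trait effects
    are absorbed individually), while rarer sites -- whose per-site
    maximum-likelihood coefficients would be dominated by noise -- are
    collapsed into a single aggregate count column.
    """
    if primary_coding is None:
        if G is None:
            raise ValueError("need either a primary coding or a genotype matrix")
        maf = G.sample_maf()
        mask = (maf > 0) & (maf <= maf_cap)
        C = G.counts[:, mask].astype(float)
        mac = C.sum(axis=0)
        well_identified = C[:, mac >= mac_min]
        cols = [well_identified]
        if (mac < mac_min).any():
            cols.append(C[:, mac < mac_min].sum(axis=1, keepdims=True))
        primary_coding = np.column_stack(cols)
    if method == "joint":
        return fit_null_joint(y1, y2, X1, X2, primary_coding, region)
    pf = fit_truncated_primary(y1, X1, primary_coding, region)
    fit, resid = fit_conditional_secondary(y2, X2, y1, pf.mu1)
    fit.gamma1 = pf.gamma1
    fit.beta_p_hat = pf.beta_p_hat
    fit.sigma1_hat = pf.sigma1_hat
    fit.converged = pf.converged
    fit.loglik = pf.loglik
    return fit, resid


def naive_bias(
    beta_p: float,
    rho: float,
    q_low: float = 0.05,
    q_high: float = 0.95,
    coding_variance: float = 1.0,
    n_nodes: int = 201,
) -> float:
    """Large-sample bias of the naive secondary-effect estimate under
    two-sided tail selection.

    Model: coding x ~ N(0, v); y1 = beta_p*x + eps1, y2 = eps2 under the
    null, (eps1, eps2) standard bivariate normal with correlation rho;
    individuals selected when y1 falls outside the (q_low, q_high)
    quantiles of its marginal.  The naive OLS slope of y2 on x in the
    selected sample converges to

        rho * Cov_sel(x, m(x)) / Var_sel(x),

    where m(x) = E[eps1 | selected, x] is the two-tail truncated-normal
    mean.  The selected-sample moments are computed by Gauss-Hermite
    quadrature over x weighted by the selection probability.
    """
    if not (0.0 < q_low < q_high < 1.0):
        raise ValueError("require 0 < q_low < q_high < 1")
    if coding_variance <= 0:
        raise ValueError("coding_variance must be positive")
    if rho == 0.0 or beta_p == 0.0:
        # selection independent of eps2, or of the coding
        return 0.0
    v = coding_variance
    sd_y1 = np.sqrt(beta_p**2 * v + 1.0)
    c_lo = stats.norm.ppf(q_low) * sd_y1
    c_hi = stats.norm.ppf(q_high) * sd_y1

    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    x = np.sqrt(2.0 * v) * t
    w = w / np.sqrt(np.pi)  # weights of N(0, v) after the change of variable
    a = c_lo - beta_p * x
    b = c_hi - beta_p * x
    logZ = np.logaddexp(stats.norm.logcdf(a), stats.norm.logsf(b))
    Z = np.exp(logZ)
    m = (stats.norm.pdf(b) - stats.norm.pdf(a)) / Z
    wsel = w * Z
    W = wsel.sum()
    Ex = (wsel * x).sum() / W
    Ex2 = (wsel * x * x).sum() / W
    Em = (wsel * m).sum() / W
    Exm = (wsel * x * m).sum() / W
    return float(rho * (Exm - Ex * Em) / (Ex2 - Ex**2))
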