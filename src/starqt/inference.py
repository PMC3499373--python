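"""Permutation inference over exchangeable residuals and analytic p-values.

Because the null-model residuals are exchangeable, the null distribution
of any region statistic is obtained by shuffling the residuals while
holding the genotypes fixed.  The empirical p-value uses the add-one
convention p = (1 + #{T_b >= T_obs}) / (B + 1), which is a valid p-value
and never returns zero.

Two-sided tests (burden family: CMC, WSS, single-variant) compare
absolute statistics; SKAT, KBAC and VT are already non-negative
quadratics/maxima and use the upper tail.

A vectorized batch engine evaluates all five region tests on a shared
permutation-index matrix: burden/SKAT/VT statistics become matrix
products of the permuted-residual matrix with coded genotype columns,
and KBAC group means are bin-counted per permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from . import rvtests
from .rvtests import GenotypeCoding, TestResult, exact_permutation_variance
from .simgen import GenotypeMatrix, as_rng

__all__ = [
    "PermutationPlan",
    "permutation_pvalue",
    "skat_analytic_p",
    "burden_analytic_p",
    "permutation_index_matrix",
    "batch_region_tests",
]

TWO_SIDED_TESTS = {"CMC", "WSS", "single"}


@dataclass
class PermutationPlan:
    B: int
    seed: int = 0
    sidedness: str = "two-sided"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("permutation count B must be >= 1")
        if self.sidedness not in ("two-sided", "one-sided-upper"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


def _empirical_p(t_obs: float, t_perm: np.ndarray, sidedness: str) -> tuple[float, float]:
    """Add-one and mid-p permutation p-value estimates."""
    if sidedness == "two-sided":
        count = int(np.sum(np.abs(t_perm) >= abs(t_obs)))
    else:
        count = int(np.sum(t_perm >= t_obs))
    B = t_perm.size
    return (1.0 + count) / (B + 1.0), (0.5 + count) / (B + 1.0)


def permutation_pvalue(statistic_fn, e, G, plan: PermutationPlan) -> TestResult:
    """Generic permutation p-value for any statistic of (residuals, genotypes).

    ``statistic_fn(e, G) -> float`` must be pure; only the residuals are
    shuffled.  Adaptive statistics (e.g. KBAC) are recomputed in full for
    every permutation simply by being called on the shuffled residuals.
    """
    e = np.asarray(e, dtype=float)
    rng = as_rng(plan.seed)
    t_obs = float(statistic_fn(e, G))
    t_perm = np.empty(plan.B)
    for b in range(plan.B):
        t_perm[b] = statistic_fn(rng.permutation(e), G)
    p, p_mid = _empirical_p(t_obs, t_perm, plan.sidedness)
    return TestResult(test="custom", statistic=t_obs, p_empirical=p, p_mid=p_mid,
                      n_perm=plan.B)


# ---------------------------------------------------------------------------
# analytic approximations
# ---------------------------------------------------------------------------

def burden_analytic_p(U: float, e, coding) -> float:
    """Two-sided normal-tail p-value for a burden score, using the exact
    permutation variance of U.  Approximate: the permutation distribution
    of U is only asymptotically normal, and can be visibly discrete when
    aggregate carrier counts are low."""
    x = coding.x if isinstance(coding, GenotypeCoding) else np.asarray(coding, dtype=float)
    var = exact_permutation_variance(e, x)
    if var == 0.0:
        warnings.warn("zero permutation variance; burden p-value set to 1")
        return 1.0
    return float(2.0 * stats.norm.sf(abs(U) / np.sqrt(var)))


def _imhof_tail(x: float, lam: np.ndarray) -> float:
    """P(sum_k lam_k chi2_1 > x) by Imhof's numerical inversion."""

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return 0.5 + val / np.pi


def _liu_tail(x: float, lam: np.ndarray) -> float:
    """Moment-matching (Liu-type) chi-square approximation fallback."""
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_q, sd_q = c1, np.sqrt(2.0 * c2)
    t = (x - mu_q) / sd_q * np.sqrt(2.0 * (df + 2.0 * delta)) + df + delta
    return float(stats.ncx2.sf(t, df, delta))


def skat_analytic_p(
    Q: float, e, G: GenotypeMatrix, weight_scheme: str = "madsen-browning",
    maf_threshold: float = 0.01,
) -> float:
    """Analytic tail probability of the SKAT quadratic form.

    Under the null, Q is approximately a mixture of chi-square(1)
    variables with weights the eigenvalues of the centered, weighted
    genotype cross-product scaled by the residual variance.  Evaluated
    by Imhof's exact numerical inversion, with a moment-matching
    fallback if the integration misbehaves.
    """
    e = np.asarray(e, dtype=float)
    if Q <= 0.0:
        return 1.0
    maf = G.sample_maf()
    mask = (maf > 0.0) & (maf <= maf_threshold)
    w = rvtests.skat_weights(G, weight_scheme)[mask]
    C = G.counts[:, mask].astype(float)
    C = (C - C.mean(axis=0)) * np.sqrt(w)
    sigma2 = float(e @ e / max(e.size - 1, 1))
    lam = np.linalg.eigvalsh(sigma2 * (C.T @ C))
    lam = lam[lam > 1e-12 * lam.max()] if lam.max() > 0 else lam
    if lam.size == 0:
        return 1.0
    if lam.size == 1:
        # one eigenvalue: the mixture is exactly a scaled chi-square(1)
        return float(stats.chi2.sf(Q / lam[0], df=1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            p = _imhof_tail(Q, lam)
        if not (-1e-8 <= p <= 1.0 + 1e-8):
            raise FloatingPointError("Imhof integration out of range")
    except Exception:
        warnings.warn("Imhof integration failed; using moment-matching approximation")
        p = _liu_tail(Q, lam)
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# vectorized batch engine for the five region tests
# ---------------------------------------------------------------------------

def permutation_index_matrix(n: int, B: int, seed=0) -> np.ndarray:
    """B independent uniform permutations of range(n), one per row."""
    rng = as_rng(seed)
    idx = np.tile(np.arange(n, dtype=np.int32), (B, 1))
    return rng.permuted(idx, axis=1)


def _batch_burden(E: np.ndarray, e: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    xc = x - x.mean()
    return float(e @ xc), E @ xc


def batch_region_tests(
    G: GenotypeMatrix,
    residuals: dict[str, np.ndarray],
    perm_idx: np.ndarray,
    maf_threshold: float = 0.01,
    vt_cap: float = 0.05,
    weight_scheme: str = "madsen-browning",
) -> dict[str, TestResult]:
    """Run CMC, WSS, KBAC, VT and SKAT with a shared permutation plan.

    ``residuals`` maps each test name to its residual vector (tests fitted
    with the same null coding may share a vector).  ``perm_idx`` is a
    (B, n) permutation-index matrix; each test's permuted statistics are
    evaluated on the same index rows, vectorized.
    """
    B, n = perm_idx.shape
    results: dict[str, TestResult] = {}
    maf = G.sample_maf()

    def permuted(e):
        return e[perm_idx]

    # --- CMC and WSS: plain burden scores, two-sided
    for name, coder in (("CMC", rvtests.code_cmc), ("WSS", rvtests.code_wss)):
        e = np.asarray(residuals[name], dtype=float)
        x = coder(G, maf_threshold).x
        t_obs, t_perm = _batch_burden(permuted(e), e, x)
        p, p_mid = _empirical_p(t_obs, t_perm, "two-sided")
        results[name] = TestResult(
            test=name, statistic=t_obs, p_empirical=p, p_mid=p_mid,
            n_perm=B, direction=int(np.sign(t_obs)),
        )

    # --- SKAT: quadratic form, upper tail
    e = np.asarray(residuals["SKAT"], dtype=float)
    mask = (maf > 0.0) & (maf <= maf_threshold)
    w = rvtests.skat_weights(G, weight_scheme)[mask]
    Csub = G.counts[:, mask].astype(float)
    q_obs = float((w * (e @ Csub) ** 2).sum())
    q_perm = ((permuted(e) @ Csub) ** 2) @ w
    p, p_mid = _empirical_p(q_obs, q_perm, "one-sided-upper")
    results["SKAT"] = TestResult(test="SKAT", statistic=q_obs, p_empirical=p,
                                 p_mid=p_mid, n_perm=B)

    # --- VT: max over thresholds of |standardized burden|, upper tail
    e = np.asarray(residuals["VT"], dtype=float)
    thresholds = rvtests.vt_thresholds(G, vt_cap)
    Xt = np.column_stack([
        G.counts[:, (maf > 0.0) & (maf <= t)].sum(axis=1).astype(float)
        for t in thresholds
    ])
    Xc = Xt - Xt.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    se_obs = np.sqrt(np.sum((e - e.mean()) ** 2) / (n - 1))
    denom = np.where(sx > 0, sx * se_obs, np.inf)
    z_obs = np.abs(e @ Xc) / denom
    t_obs = float(z_obs.max())
    z_perm = np.abs(permuted(e) @ Xc) / denom  # (B, T); residual SS is permutation-invariant
    t_perm = z_perm.max(axis=1)
    p, p_mid = _empirical_p(t_obs, t_perm, "one-sided-upper")
    results["VT"] = TestResult(
        test="VT", statistic=t_obs, p_empirical=p, p_mid=p_mid, n_perm=B,
        vt_threshold=float(thresholds[int(z_obs.argmax())]),
    )

    # --- KBAC: adaptive weights recomputed per permutation, upper tail
    e = np.asarray(residuals["KBAC"], dtype=float)
    sub = G.counts[:, mask]
    groups, inverse = np.unique(sub, axis=0, return_inverse=True)
    if groups.shape[0] < 2:
        results["KBAC"] = TestResult(test="KBAC", statistic=0.0, p_empirical=1.0,
                                     p_mid=1.0, n_perm=B)
        return results
    n_k = np.bincount(inverse)
    keep = groups.any(axis=1)  # drop the all-zero (null) genotype group
    sigma = e.std(ddof=1)
    root_nk = np.sqrt(n_k)

    def kbac_from_sums(sums):
        ebar = sums / n_k
        w_k = stats.norm.cdf(ebar * root_nk / sigma)
        return (w_k[keep] * n_k[keep] * ebar[keep]).sum()

    t_obs = float(kbac_from_sums(np.bincount(inverse, weights=e)))
    E = permuted(e)
    t_perm = np.empty(B)
    for b in range(B):
        t_perm[b] = kbac_from_sums(np.bincount(inverse, weights=E[b]))
    p, p_mid = _empirical_p(t_obs, t_perm, "one-sided-upper")
    results["KBAC"] = TestResult(test="KBAC", statistic=t_obs, p_empirical=p,
                                 p_mid=p_mid, n_perm=B)
    return results
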