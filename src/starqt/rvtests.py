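"""Region-based rare-variant test statistics on exchangeable residuals.

Every statistic is a function of the secondary-trait residuals ``e``
(from the ascertainment-corrected null fit) and the genotype matrix of
the analyzed region.  Burden-type statistics are score statistics

    U = sum_i e_i * (x_i - mean(x)),

proportional to the sample covariance between residuals and a scalar
genotype coding x; SKAT is the quadratic form Q = e' K e with a weighted
linear kernel; VT maximizes a standardized burden score over the
observed MAF thresholds; KBAC adaptively weights multi-site genotype
groups by their evidence of trait shift.

Site minor-allele frequencies are the empirical frequencies in the
analyzed sample; monomorphic columns carry zero information and never
contribute to a coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simgen import GenotypeMatrix

__all__ = [
    "GenotypeCoding",
    "TestResult",
    "code_cmc",
    "code_wss",
    "burden_score",
    "vt_statistic",
    "skat_statistic",
    "skat_weights",
    "kbac_qt_statistic",
    "single_variant_score",
    "TESTS",
]

#: The five region tests of the framework, in canonical order.
TESTS = ("CMC", "WSS", "KBAC", "VT", "SKAT")


@dataclass
class GenotypeCoding:
    """A per-individual scalar coding of the region multi-site genotypes."""

    x: np.ndarray
    weights: np.ndarray | None = None
    maf_threshold: float = 0.01
    depends_on_trait: bool = False


@dataclass
class TestResult:
    test: str
    statistic: float
    p_empirical: float
    n_perm: int
    p_analytic: float | None = None
    vt_threshold: float | None = None
    direction: int = 0
    #: mid-p estimate (count + 0.5)/(B + 1): unbiased under the discrete
    #: permutation null, preferred for Z-transformation in meta-analysis;
    #: p_empirical (add-one) remains the reported valid p-value.
    p_mid: float | None = None


def _qualifying_mask(G: GenotypeMatrix, maf_threshold: float) -> np.ndarray:
    maf = G.sample_maf()
    return (maf > 0.0) & (maf <= maf_threshold)


def code_cmc(G: GenotypeMatrix, maf_threshold: float = 0.01) -> GenotypeCoding:
    """Collapsing indicator: carries >= 1 minor allele at any rare site."""
    if not (0.0 < maf_threshold <= 0.5):
        raise ValueError("maf_threshold must be in (0, 0.5]")
    mask = _qualifying_mask(G, maf_threshold)
    if not mask.any():
        raise ValueError(
            f"no polymorphic site with MAF <= {maf_threshold} qualifies for collapsing"
        )
    x = (G.counts[:, mask] > 0).any(axis=1).astype(float)
    return GenotypeCoding(x=x, weights=None, maf_threshold=maf_threshold)


def wss_weights(G: GenotypeMatrix) -> np.ndarray:
    """Madsen-Browning weights w_j = 1/sqrt(n q_j (1 - q_j)) with the
    pseudo-count frequency estimator q_j = (c_j + 1) / (2n + 2) from the
    whole analyzed sample (trait-independent)."""
    n = G.n_individuals
    c = G.counts.sum(axis=0)
    q = (c + 1.0) / (2.0 * n + 2.0)
    return 1.0 / np.sqrt(n * q * (1.0 - q))


def code_wss(G: GenotypeMatrix, maf_threshold: float = 0.01) -> GenotypeCoding:
    """Weighted-sum coding: x_i = sum_j w_j g_ij over qualifying sites.

    Monomorphic sites get a finite weight (pseudo-count) but contribute
    zero to every individual's score.
    """
    if G.n_individuals < 2:
        raise ValueError("need at least two individuals")
    maf = G.sample_maf()
    mask = maf <= maf_threshold  # monomorphic columns included; they add 0
    w = wss_weights(G)
    x = G.counts[:, mask].astype(float) @ w[mask]
    return GenotypeCoding(x=x, weights=w, maf_threshold=maf_threshold)


def burden_score(e, coding: GenotypeCoding | np.ndarray) -> float:
    """Score statistic U = sum_i e_i (x_i - mean(x))."""
    e = np.asarray(e, dtype=float)
    x = coding.x if isinstance(coding, GenotypeCoding) else np.asarray(coding, dtype=float)
    if e.size != x.size:
        raise ValueError("residuals and coding have different lengths")
    if np.ptp(x) == 0.0:
        warnings.warn("constant genotype coding; burden score is 0")
        return 0.0
    return float(e @ (x - x.mean()))


def exact_permutation_variance(e, x) -> float:
    """Exact variance of U under uniform permutation of e given (e, x):
    Var = sum (e - ebar)^2 * sum (x - xbar)^2 / (n - 1)."""
    e = np.asarray(e, dtype=float)
    x = np.asarray(x, dtype=float)
    n = e.size
    return float(np.sum((e - e.mean()) ** 2) * np.sum((x - x.mean()) ** 2) / (n - 1))


def vt_thresholds(G: GenotypeMatrix, maf_cap: float = 0.05) -> np.ndarray:
    maf = G.sample_maf()
    t = np.unique(maf[(maf > 0.0) & (maf <= maf_cap)])
    if t.size == 0:
        raise ValueError(f"no polymorphic site with MAF <= {maf_cap}; VT is undefined")
    return t


def vt_statistic(e, G: GenotypeMatrix, maf_cap: float = 0.05) -> tuple[float, float]:
    """Variable-threshold statistic.

    For each distinct observed MAF t <= maf_cap, the unweighted allele
    count over sites with MAF <= t gives a burden score U(t), which is
    standardized by its exact permutation SD; the statistic is the
    maximum of |z(t)| and the selected threshold is its argmax.
    """
    e = np.asarray(e, dtype=float)
    thresholds = vt_thresholds(G, maf_cap)
    maf = G.sample_maf()
    t_max, arg = -np.inf, thresholds[0]
    for t in thresholds:
        x = G.counts[:, (maf > 0.0) & (maf <= t)].sum(axis=1).astype(float)
        var = exact_permutation_variance(e, x)
        z = 0.0 if var == 0.0 else abs(e @ (x - x.mean())) / np.sqrt(var)
        if z > t_max:
            t_max, arg = z, t
    return float(t_max), float(arg)


def skat_weights(G: GenotypeMatrix, scheme: str = "madsen-browning") -> np.ndarray:
    """Per-site kernel weights.

    'madsen-browning': w_j = 1 / (q_j (1 - q_j)) with the pseudo-count
    frequency estimator (the squared Madsen-Browning functional form);
    'beta': w_j = Beta(1, 25).pdf(maf_j)^2, the common SKAT default.
    """
    n = G.n_individuals
    c = G.counts.sum(axis=0)
    q = (c + 1.0) / (2.0 * n + 2.0)
    if scheme == "madsen-browning":
        return 1.0 / (q * (1.0 - q))
    if scheme == "beta":
        return stats.beta.pdf(np.minimum(q, 0.5), 1, 25) ** 2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def skat_statistic(
    e, G: GenotypeMatrix, weight_scheme: str = "madsen-browning", maf_threshold: float = 0.01
) -> float:
    """Variance-component score statistic Q = sum_j w_j (sum_i e_i g_ij)^2,
    the quadratic form e' K e with the weighted linear kernel."""
    e = np.asarray(e, dtype=float)
    mask = _qualifying_mask(G, maf_threshold)
    if not mask.any():
        raise ValueError(f"no polymorphic site with MAF <= {maf_threshold} for SKAT")
    w = skat_weights(G, weight_scheme)[mask]
    scores = e @ G.counts[:, mask].astype(float)
    return float((w * scores**2).sum())


def kbac_qt_statistic(e, G: GenotypeMatrix, maf_threshold: float = 0.01) -> float:
    """Kernel-based adaptive cluster statistic for quantitative traits.

    Individuals are grouped by their distinct multi-site rare genotype.
    Group k (n_k members, mean residual ebar_k) receives the adaptive
    weight w_k = Phi(ebar_k * sqrt(n_k) / sigma_hat) -- the estimated
    probability that the genotype raises the trait -- and the statistic
    is T = sum over non-null genotype groups of w_k * n_k * ebar_k.
    Weights depend on the residuals, so they are recomputed inside every
    permutation.
    """
    e = np.asarray(e, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two individuals")
    mask = _qualifying_mask(G, maf_threshold)
    sub = G.counts[:, mask]
    groups, inverse = np.unique(sub, axis=0, return_inverse=True)
    if groups.shape[0] < 2:
        warnings.warn("all individuals share one multi-site genotype; KBAC statistic is 0")
        return 0.0
    sigma = e.std(ddof=1)
    if sigma == 0.0:
        return 0.0
    n_k = np.bincount(inverse)
    sums = np.bincount(inverse, weights=e)
    ebar = sums / n_k
    w = stats.norm.cdf(ebar * np.sqrt(n_k) / sigma)
    null_rows = ~groups.any(axis=1)  # the all-zero (non-carrier) genotype
    keep = ~null_rows
    return float((w[keep] * n_k[keep] * ebar[keep]).sum())


def single_variant_score(e, g_j) -> float:
    """Burden score with the coding equal to a single site's counts."""
    g = np.asarray(g_j, dtype=float)
    if np.ptp(g) == 0.0:
        raise ValueError("site is monomorphic in the sample")
    return burden_score(e, g)
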