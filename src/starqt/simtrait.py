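"""Bivariate quantitative-trait simulation and phenotype preprocessing.

The trait model: for individual i with genotype row g_i and covariates,

    y1_i = X1_i @ gamma1 + sum_j beta_p[j] * g_ij + eps1_i     (primary)
    y2_i = X2_i @ gamma2 + sum_j beta_s[j] * g_ij + eps2_i     (secondary)

with (eps1, eps2) bivariate normal, standard deviations (sigma1, sigma2)
and residual correlation rho.  Causal sites are drawn from the
deleterious pool (selection coefficient above the eligibility cutoff),
independently for the two traits, so their intersection is pleiotropic.

Also provides the phenotype preprocessing used for real selected-sample
data: medication adjustment of blood pressure and covariate-adjusted
quantile normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simgen import DELETERIOUS_S, GenotypeMatrix, VariantSite, as_rng

__all__ = [
    "EffectProfile",
    "TraitModel",
    "CohortPhenotypes",
    "select_causal_sets",
    "effect_sizes",
    "simulate_traits",
    "adjust_medication",
    "covariate_adjust_quantile_normalize",
]


@dataclass
class EffectProfile:
    """Per-site genetic effects for the two traits (trait-SD units per
    minor allele; exactly zero at non-causal sites)."""

    beta_primary: np.ndarray
    beta_secondary: np.ndarray
    model: str = "fixed"
    magnitude_params: tuple[float, float] = (0.0, 0.0)
    frac_positive: float = 1.0

    def __post_init__(self):
        self.beta_primary = np.asarray(self.beta_primary, dtype=float)
        self.beta_secondary = np.asarray(self.beta_secondary, dtype=float)
        if self.beta_primary.shape != self.beta_secondary.shape:
            raise ValueError("effect vectors must have equal length")


@dataclass
class TraitModel:
    """Residual structure of the bivariate trait model."""

    rho: float = 0.6
    sigma1: float = 1.0
    sigma2: float = 1.0
    gamma1: np.ndarray | None = None
    gamma2: np.ndarray | None = None

    def __post_init__(self):
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [-1, 1]")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("residual SDs must be positive")


@dataclass
class CohortPhenotypes:
    y1: np.ndarray
    y2: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self):
        self.y1 = np.asarray(self.y1, dtype=float)
        self.y2 = np.asarray(self.y2, dtype=float)
        if self.y1.shape != self.y2.shape:
            raise ValueError("y1 and y2 must have equal length")


def select_causal_sets(
    sites: list[VariantSite], proportion: float, seed=0, eligibility_s: float = DELETERIOUS_S
) -> tuple[np.ndarray, np.ndarray]:
    """Independently draw primary- and secondary-trait causal site sets.

    Eligible sites are those under purifying selection (sel_coeff above
    ``eligibility_s``).  Each set contains floor(proportion * n_eligible)
    sites drawn uniformly without replacement; the two draws are
    independent, so the intersection (pleiotropic sites) has
    hypergeometric size.  Causal flags are set on the site objects.
    """
    if not (0.0 < proportion <= 1.0):
        raise ValueError("proportion must be in (0, 1]")
    eligible = np.array([j for j, s in enumerate(sites) if s.sel_coeff > eligibility_s])
    if eligible.size == 0:
        raise ValueError(
            f"no eligible causal sites: no site has sel_coeff > {eligibility_s}"
        )
    k = int(np.floor(proportion * eligible.size))
    rng = as_rng(seed)
    cp = np.sort(rng.choice(eligible, size=k, replace=False))
    cs = np.sort(rng.choice(eligible, size=k, replace=False))
    for s in sites:
        s.causal_primary = False
        s.causal_secondary = False
    for j in cp:
        sites[j].causal_primary = True
    for j in cs:
        sites[j].causal_secondary = True
    return cp, cs


def effect_sizes(
    sites: list[VariantSite],
    causal,
    model: str = "fixed",
    c1: float = 0.5,
    c2: float = 0.0,
    frac_positive: float = 1.0,
    seed=0,
) -> np.ndarray:
    """Per-site effect vector for one trait.

    Magnitude |beta_j| = c1 (model='fixed') or c1 + c2*|log10 maf_j|
    (model='log-maf'), so rarer variants get larger effects.  Exactly
    round(frac_positive * n_causal) causal sites get a positive sign
    (which ones is a seeded draw); non-causal sites are exactly zero.
    """
    if c1 < 0:
        raise ValueError("c1 must be >= 0")
    if not (0.0 <= frac_positive <= 1.0):
        raise ValueError("frac_positive must be in [0, 1]")
    if model not in ("fixed", "log-maf"):
        raise ValueError(f"unknown effect model {model!r}")
    causal = np.asarray(sorted(causal), dtype=int)
    beta = np.zeros(len(sites))
    if causal.size == 0:
        return beta
    mafs = np.array([sites[j].maf for j in causal])
    mag = np.full(causal.size, c1) if model == "fixed" else c1 + c2 * np.abs(np.log10(mafs))
    n_pos = int(round(frac_positive * causal.size))
    sign = np.full(causal.size, -1.0)
    rng = as_rng(seed)
    pos = rng.choice(causal.size, size=n_pos, replace=False)
    sign[pos] = 1.0
    beta[causal] = sign * mag
    return beta


def simulate_traits(
    G: GenotypeMatrix,
    effects: EffectProfile,
    tm: TraitModel,
    covariates: np.ndarray | None = None,
    seed=0,
) -> CohortPhenotypes:
    """Simulate (y1, y2) for every individual under the bivariate model."""
    n, m = G.counts.shape
    if effects.beta_primary.size != m:
        raise ValueError(
            f"effect vectors have {effects.beta_primary.size} entries for {m} sites"
        )
    rng = as_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    eps1 = tm.sigma1 * z1
    eps2 = tm.sigma2 * (tm.rho * z1 + np.sqrt(1.0 - tm.rho**2) * z2)
    counts = G.counts.astype(float)
    y1 = counts @ effects.beta_primary + eps1
    y2 = counts @ effects.beta_secondary + eps2
    if covariates is not None:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("covariate rows do not match number of individuals")
        if tm.gamma1 is not None:
            y1 = y1 + X @ np.asarray(tm.gamma1, dtype=float)
        if tm.gamma2 is not None:
            y2 = y2 + X @ np.asarray(tm.gamma2, dtype=float)
    return CohortPhenotypes(y1, y2, covariates)


def adjust_medication(bp, medicated, delta: float) -> np.ndarray:
    """Add ``delta`` to the blood pressure of medicated individuals.

    Standard correction for antihypertensive treatment before analysis
    (e.g. +10 mmHg systolic, +5 mmHg diastolic).
    """
    bp = np.asarray(bp, dtype=float)
    medicated = np.asarray(medicated, dtype=bool)
    if bp.shape != medicated.shape:
        raise ValueError("bp and medicated must have the same length")
    return np.where(medicated, bp + delta, bp)


def covariate_adjust_quantile_normalize(trait, covariates=None) -> np.ndarray:
    """Residualize a trait on covariates, then map residual ranks onto
    normal scores Phi^{-1}((rank - 0.5) / n).

    Ties receive average ranks before the transform.  An intercept is
    always included; a rank-deficient covariate matrix is rejected.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C])
    if n <= X.shape[1]:
        raise ValueError("need more observations than covariate columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinear columns)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ranks = stats.rankdata(resid, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)
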