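"""Rare-variant region genotype simulation.

Generates per-site minor allele frequencies from a configurable site
frequency spectrum (SFS), annotates sites with selection coefficients
(rarer sites are more likely deleterious), and draws independent-site
Hardy-Weinberg genotypes.  This is a desk-scale stand-in for a forward
population-genetic simulation: it preserves the two properties the
downstream association method consumes -- a rare-skewed frequency
spectrum and a deleterious-site labelling -- without modelling
demography, linkage disequilibrium or recurrent mutation.  Externally
computed per-site (MAF, selection coefficient) tables can be supplied
via :func:`sites_from_table` so a forward simulator can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VariantSite",
    "GenotypeMatrix",
    "SfsConfig",
    "draw_site_frequencies",
    "assign_selection_coeffs",
    "sample_genotypes",
    "simulate_region",
    "sites_from_table",
    "DELETERIOUS_S",
]

#: Selection-coefficient cutoff above which a site is considered deleterious
#: (and thus eligible to be causal in trait simulations).
DELETERIOUS_S = 1e-4


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class VariantSite:
    """A biallelic variant site, oriented to the minor allele."""

    site_id: str
    maf: float
    sel_coeff: float = 0.0
    causal_primary: bool = False
    causal_secondary: bool = False

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"site {self.site_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.sel_coeff < 0:
            raise ValueError(f"site {self.site_id}: sel_coeff must be >= 0")


@dataclass
class GenotypeMatrix:
    """Individuals x sites minor-allele counts with site annotations.

    ``counts[i, j]`` is the number of minor alleles (0/1/2) carried by
    individual ``i`` at site ``j``.  Columns may be monomorphic in a
    drawn cohort; they are retained (stable indexing) but carry zero
    information and are excluded from test codings downstream.
    """

    counts: np.ndarray
    sites: list[VariantSite] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional (individuals x sites)")
        if self.counts.size and not (
            np.issubdtype(self.counts.dtype, np.integer)
            and self.counts.min() >= 0
            and self.counts.max() <= 2
        ):
            raise ValueError("genotype counts must be integers in {0, 1, 2}")
        if self.sites and len(self.sites) != self.counts.shape[1]:
            raise ValueError("number of sites does not match count columns")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    def sample_maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per site, from the counts."""
        return self.counts.mean(axis=0) / 2.0

    def subset(self, indices) -> "GenotypeMatrix":
        """Row subset (e.g. the ascertained individuals)."""
        return GenotypeMatrix(self.counts[np.asarray(indices)], self.sites)


@dataclass
class SfsConfig:
    """Configuration of the site-frequency-spectrum generator.

    spectrum='reciprocal' draws MAFs with density proportional to 1/x on
    [maf_min, maf_max], the classic rare-skewed neutral-like spectrum.
    spectrum='custom-grid' draws from a supplied (grid_mafs, grid_weights)
    discrete table.
    """

    n_sites: int
    spectrum: str = "reciprocal"
    maf_min: float = 1e-4
    maf_max: float = 0.5
    seed: int = 0
    grid_mafs: np.ndarray | None = None
    grid_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0.0 < self.maf_min < self.maf_max <= 0.5):
            raise ValueError(
                f"require 0 < maf_min < maf_max <= 0.5, got ({self.maf_min}, {self.maf_max})"
            )
        if self.spectrum not in ("reciprocal", "custom-grid"):
            raise ValueError(f"unknown spectrum {self.spectrum!r}")
        if self.spectrum == "custom-grid" and self.grid_mafs is None:
            raise ValueError("custom-grid spectrum requires grid_mafs")


def draw_site_frequencies(cfg: SfsConfig, rng=None) -> np.ndarray:
    """Draw per-site MAFs from the configured spectrum.

    Reciprocal spectrum via inverse-CDF: x = maf_min * (maf_max/maf_min)**u
    with u uniform, which has density proportional to 1/x.
    """
    rng = as_rng(cfg.seed if rng is None else rng)
    if cfg.spectrum == "reciprocal":
        u = rng.random(cfg.n_sites)
        return cfg.maf_min * (cfg.maf_max / cfg.maf_min) ** u
    grid = np.asarray(cfg.grid_mafs, dtype=float)
    if not ((grid > 0) & (grid <= 0.5)).all():
        raise ValueError("grid_mafs must lie in (0, 0.5]")
    w = cfg.grid_weights
    if w is not None:
        w = np.asarray(w, dtype=float)
        w = w / w.sum()
    return rng.choice(grid, size=cfg.n_sites, p=w)


# Deleterious-probability anchors: P(s > DELETERIOUS_S) interpolates
# log-linearly in MAF between these two points (and is clipped outside).
_P_DEL_AT_RAREST = 0.90  # at MAF = 1e-4
_P_DEL_AT_COMMON = 0.05  # at MAF = 0.5


def deleterious_probability(mafs: np.ndarray) -> np.ndarray:
    """P(site is deleterious | MAF): decreasing log-linearly in MAF."""
    mafs = np.asarray(mafs, dtype=float)
    lo, hi = np.log10(1e-4), np.log10(0.5)
    t = (np.log10(mafs) - lo) / (hi - lo)
    p = _P_DEL_AT_RAREST + t * (_P_DEL_AT_COMMON - _P_DEL_AT_RAREST)
    return np.clip(p, _P_DEL_AT_COMMON, _P_DEL_AT_RAREST)


def assign_selection_coeffs(mafs, seed=0) -> np.ndarray:
    """Assign non-negative selection coefficients to sites.

    With probability decreasing in MAF a site is deleterious
    (s > DELETERIOUS_S, drawn as DELETERIOUS_S plus an exponential with
    mean 1e-2); otherwise s is uniform on [0, DELETERIOUS_S].
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size == 0:
        return np.empty(0)
    if not ((mafs > 0) & (mafs <= 0.5)).all():
        raise ValueError("mafs must lie in (0, 0.5]")
    rng = as_rng(seed)
    deleterious = rng.random(mafs.size) < deleterious_probability(mafs)
    s = rng.uniform(0.0, DELETERIOUS_S, size=mafs.size)
    s[deleterious] = DELETERIOUS_S + rng.exponential(1e-2, size=int(deleterious.sum()))
    return s


def sample_genotypes(mafs, n: int, seed=0, sites: list[VariantSite] | None = None) -> GenotypeMatrix:
    """Draw an n x m genotype matrix with entries Binomial(2, maf_j).

    Sites are independent (no linkage disequilibrium) and in
    Hardy-Weinberg proportions by construction.
    """
    mafs = np.asarray(mafs, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not ((mafs > 0) & (mafs <= 0.5)).all():
        raise ValueError("mafs must lie in (0, 0.5]")
    rng = as_rng(seed)
    # Binomial(2, p) as two Bernoulli draws: much faster than rng.binomial
    # with a per-column p array at cohort scale
    m = mafs.size
    p32 = mafs.astype(np.float32)
    counts = (rng.random((n, m), dtype=np.float32) < p32).view(np.int8) \
        + (rng.random((n, m), dtype=np.float32) < p32).view(np.int8)
    if sites is None:
        sites = [VariantSite(site_id=f"s{j}", maf=m) for j, m in enumerate(mafs)]
    return GenotypeMatrix(counts, sites)


def simulate_region(cfg: SfsConfig, n: int, seed=None) -> GenotypeMatrix:
    """Full region draw: frequencies -> selection coefficients -> genotypes."""
    rng = as_rng(cfg.seed if seed is None else seed)
    mafs = draw_site_frequencies(cfg, rng=rng)
    s = assign_selection_coeffs(mafs, seed=rng)
    sites = [
        VariantSite(site_id=f"s{j}", maf=m, sel_coeff=sj)
        for j, (m, sj) in enumerate(zip(mafs, s))
    ]
    return sample_genotypes(mafs, n, seed=rng, sites=sites)


def sites_from_table(mafs, sel_coeffs, site_ids=None) -> list[VariantSite]:
    """Hook: build the site list from an externally supplied MAF/selection
    table (e.g. the output of a forward simulator)."""
    mafs = np.asarray(mafs, dtype=float)
    sel = np.asarray(sel_coeffs, dtype=float)
    if mafs.shape != sel.shape:
        raise ValueError("mafs and sel_coeffs must have the same length")
    if site_ids is None:
        site_ids = [f"s{j}" for j in range(mafs.size)]
    return [VariantSite(i, m, s) for i, m, s in zip(site_ids, mafs, sel)]
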