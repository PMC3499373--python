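"""Type-I-error, power and meta-analysis simulation experiments.

Each replicate simulates a rare-variant region for a full cohort, draws
bivariate traits, selects the extreme tails of the primary trait, fits
the ascertainment-corrected null model and runs the five region tests
with shared permutation inference.  Rejection rates at the nominal level
estimate type-I error (null secondary effects) or power (non-zero
secondary effects).

The default design follows the standard extreme-sampling benchmark:
5,000 selected from a cohort of 100,000 (single study), or three studies
of 2,500 selected from 50,000 each for the meta-analysis, with
primary-trait effects and residual correlations (-0.5, 0.6), (0.25, 0.4)
and (0, -0.2).

Null-model codings per test: the CMC test uses the collapsing indicator
as the primary-trait nuisance coding; WSS, SKAT and KBAC share the
Madsen-Browning weighted-sum coding; VT uses the unweighted allele count
below its MAF cap.  A 'naive' residual mode (secondary trait centred,
ascertainment ignored) is provided as the biased comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import inference, nullmodel, rvtests, simgen, simtrait
from .ascertain import select_extremes
from .meta import DIRECTIONAL_TESTS, StudySummary, combine_z
from .rvtests import TESTS

__all__ = [
    "Scenario",
    "ExperimentConfig",
    "ExperimentReport",
    "MetaStudyConfig",
    "run_type1",
    "run_power",
    "run_meta_experiment",
    "qq_data",
    "DESK_PRESET",
    "FULL_PRESET",
]

DESK_PRESET = {"replicates": 500, "permutations": 500}
FULL_PRESET = {"replicates": 10_000, "permutations": 5_000}


@dataclass
class Scenario:
    """Genetic architecture of one simulated study."""

    beta_p: float = 0.5           # signed primary-trait effect magnitude (fixed model)
    beta_s: float = 0.0           # secondary-trait effect magnitude
    rho: float = 0.6              # residual trait correlation
    frac_positive_p: float = 1.0  # sign mix of primary causal effects
    frac_positive_s: float = 1.0  # sign mix of secondary causal effects
    effect_model: str = "fixed"   # 'fixed' or 'log-maf'
    c2: float = 0.0               # MAF-dependent magnitude slope (log-maf model)
    causal_proportion: float = 0.5


@dataclass
class ExperimentConfig:
    cohort_n: int = 100_000
    select_n: int = 5_000
    replicates: int = 500
    permutations: int = 500
    alpha: float = 0.05
    n_sites: int = 60
    maf_min: float = 1e-4
    maf_max: float = 0.5
    maf_threshold: float = 0.01
    vt_cap: float = 0.05
    scenario: Scenario = field(default_factory=Scenario)
    seed: int = 0
    residual_mode: str = "star"   # 'star' or 'naive'

    def __post_init__(self):
        if self.select_n > self.cohort_n:
            raise ValueError("select_n must not exceed cohort_n")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.residual_mode not in ("star", "naive"):
            raise ValueError(f"unknown residual mode {self.residual_mode!r}")


@dataclass
class ExperimentReport:
    rejection_rate: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, np.ndarray]
    replicates: int
    alpha: float

    @staticmethod
    def from_pvalues(pvalues: dict[str, np.ndarray], alpha: float) -> "ExperimentReport":
        rates, ses = {}, {}
        reps = 0
        for test, p in pvalues.items():
            p = np.asarray(p)
            reps = p.size
            r = float(np.mean(p <= alpha))
            rates[test] = r
            ses[test] = float(np.sqrt(r * (1.0 - r) / p.size))
        return ExperimentReport(rates, ses, {k: np.asarray(v) for k, v in pvalues.items()},
                                reps, alpha)


def _simulate_study(cfg: ExperimentConfig, scen: Scenario, rng: np.random.Generator):
    """One replicate: region + traits + ascertainment. Returns (G_sel, y1, y2, region)."""
    sfs = simgen.SfsConfig(n_sites=cfg.n_sites, maf_min=cfg.maf_min, maf_max=cfg.maf_max)
    G = simgen.simulate_region(sfs, cfg.cohort_n, seed=rng)
    cp, cs = simtrait.select_causal_sets(G.sites, scen.causal_proportion, seed=rng)
    beta_p = simtrait.effect_sizes(
        G.sites, cp, model=scen.effect_model, c1=abs(scen.beta_p), c2=scen.c2,
        frac_positive=scen.frac_positive_p if scen.beta_p >= 0 else 1 - scen.frac_positive_p,
        seed=rng,
    )
    beta_s = simtrait.effect_sizes(
        G.sites, cs, model=scen.effect_model, c1=abs(scen.beta_s), c2=scen.c2,
        frac_positive=scen.frac_positive_s if scen.beta_s >= 0 else 1 - scen.frac_positive_s,
        seed=rng,
    )
    # a zero headline effect means "no association", even under the log-maf model
    if scen.beta_p == 0.0:
        beta_p[:] = 0.0
    if scen.beta_s == 0.0:
        beta_s[:] = 0.0
    effects = simtrait.EffectProfile(beta_primary=beta_p, beta_secondary=beta_s,
                                     model=scen.effect_model)
    tm = simtrait.TraitModel(rho=scen.rho)
    ph = simtrait.simulate_traits(G, effects, tm, seed=rng)
    asc = select_extremes(ph.y1, cfg.select_n)
    G_sel = G.subset(asc.indices)
    return G_sel, ph.y1[asc.indices], ph.y2[asc.indices], asc.region


def _residuals_by_test(cfg: ExperimentConfig, G_sel, y1, y2, region) -> dict[str, np.ndarray]:
    """Null-model residuals, shared by all five tests.

    The truncated primary fit uses the per-variant multivariate coding
    over every polymorphic site up to the VT cap, so per-site
    primary-trait effects are absorbed individually; one residual vector
    serves all tests.  'naive' mode ignores ascertainment entirely.
    """
    if cfg.residual_mode == "naive":
        e = y2 - y2.mean()
        return {t: e for t in TESTS}
    _, resid = nullmodel.compute_residuals(
        y1, y2, None, None, G_sel, None, region, maf_cap=cfg.vt_cap
    )
    return {t: resid.e for t in TESTS}


def _run_replicates(cfg: ExperimentConfig):
    """Shared replicate loop; returns per-test p-value arrays and directions."""
    ss = np.random.SeedSequence(cfg.seed)
    perm_seed, *rep_seeds = ss.spawn(cfg.replicates + 1)
    perm_idx = inference.permutation_index_matrix(
        cfg.select_n, cfg.permutations, seed=np.random.default_rng(perm_seed)
    )
    pvals = {t: np.empty(cfg.replicates) for t in TESTS}
    dirs = {t: np.empty(cfg.replicates, dtype=int) for t in TESTS}
    for r, child in enumerate(rep_seeds):
        rng = np.random.default_rng(child)
        G_sel, y1, y2, region = _simulate_study(cfg, cfg.scenario, rng)
        residuals = _residuals_by_test(cfg, G_sel, y1, y2, region)
        results = inference.batch_region_tests(
            G_sel, residuals, perm_idx,
            maf_threshold=cfg.maf_threshold, vt_cap=cfg.vt_cap,
        )
        for t in TESTS:
            pvals[t][r] = results[t].p_empirical
            dirs[t][r] = results[t].direction
    return pvals, dirs


def run_type1(cfg: ExperimentConfig) -> ExperimentReport:
    """Type-I-error experiment: requires zero secondary-trait effects."""
    if cfg.scenario.beta_s != 0.0:
        raise ValueError("type-I configuration requires zero secondary effects")
    pvals, _ = _run_replicates(cfg)
    return ExperimentReport.from_pvalues(pvals, cfg.alpha)


def run_power(cfg: ExperimentConfig) -> ExperimentReport:
    """Power experiment: requires non-zero secondary-trait effects."""
    if cfg.scenario.beta_s == 0.0:
        raise ValueError("power configuration requires non-zero secondary effects"
                         " (use run_type1 for the null)")
    pvals, _ = _run_replicates(cfg)
    return ExperimentReport.from_pvalues(pvals, cfg.alpha)


@dataclass
class MetaStudyConfig:
    """One study block of the three-study meta-analysis design."""

    beta_p: float
    rho: float
    cohort_n: int = 50_000
    select_n: int = 2_500


DEFAULT_META_STUDIES = (
    MetaStudyConfig(beta_p=-0.5, rho=0.6),
    MetaStudyConfig(beta_p=0.25, rho=0.4),
    MetaStudyConfig(beta_p=0.0, rho=-0.2),
)


def run_meta_experiment(
    cfg: ExperimentConfig,
    studies: tuple[MetaStudyConfig, ...] = DEFAULT_META_STUDIES,
    beta_s: float = 0.0,
    frac_positive_s: float = 1.0,
) -> dict[str, ExperimentReport]:
    """Three-study meta-analysis experiment.

    Each replicate simulates every study from an independent pool,
    analyzes it with all five tests, and combines the per-study p-values
    with sqrt(n)-weighted Z scores (directional for the burden family,
    direction-free otherwise).  Returns per-study reports plus the
    combined 'meta' report.
    """
    ss = np.random.SeedSequence(cfg.seed)
    n_studies = len(studies)
    perm_seeds = ss.spawn(n_studies)
    perm_idx = [
        inference.permutation_index_matrix(
            st.select_n, cfg.permutations, seed=np.random.default_rng(s)
        )
        for st, s in zip(studies, perm_seeds)
    ]
    rep_seeds = ss.spawn(cfg.replicates)
    study_p = [{t: np.empty(cfg.replicates) for t in TESTS} for _ in studies]
    meta_p = {t: np.empty(cfg.replicates) for t in TESTS}
    for r, child in enumerate(rep_seeds):
        study_rngs = [np.random.default_rng(s) for s in child.spawn(n_studies)]
        per_study: list[dict[str, rvtests.TestResult]] = []
        for k, (st, rng) in enumerate(zip(studies, study_rngs)):
            scen = replace(
                cfg.scenario, beta_p=st.beta_p, rho=st.rho,
                beta_s=beta_s, frac_positive_s=frac_positive_s,
            )
            sub_cfg = replace(cfg, cohort_n=st.cohort_n, select_n=st.select_n, scenario=scen)
            G_sel, y1, y2, region = _simulate_study(sub_cfg, scen, rng)
            residuals = _residuals_by_test(sub_cfg, G_sel, y1, y2, region)
            results = inference.batch_region_tests(
                G_sel, residuals, perm_idx[k],
                maf_threshold=cfg.maf_threshold, vt_cap=cfg.vt_cap,
            )
            per_study.append(results)
            for t in TESTS:
                study_p[k][t][r] = results[t].p_empirical
        for t in TESTS:
            directional = t in DIRECTIONAL_TESTS
            # mid-p feeds the Z transform: the add-one estimator is valid
            # but conservatively biased, and the bias would compound
            # sqrt(n_studies)-fold in the weighted-Z combination
            summaries = [
                StudySummary(p=per_study[k][t].p_mid,
                             direction=per_study[k][t].direction if directional else 0,
                             n=studies[k].select_n, study_id=f"study{k + 1}")
                for k in range(n_studies)
            ]
            _, meta_p[t][r] = combine_z(summaries, directional)
    out = {
        f"study{k + 1}": ExperimentReport.from_pvalues(study_p[k], cfg.alpha)
        for k in range(n_studies)
    }
    out["meta"] = ExperimentReport.from_pvalues(meta_p, cfg.alpha)
    return out


def qq_data(pvalues) -> tuple[np.ndarray, np.ndarray]:
    """Expected-vs-observed coordinates for a QQ plot of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    observed = np.sort(p)
    expected = (np.arange(1, p.size + 1) - 0.5) / p.size
    return expected, observed
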