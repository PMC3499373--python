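"""Weighted-Z (Stouffer) meta-analysis across differently ascertained cohorts.

Per-study p-values are transformed to Z scores and combined weighted by
the square root of the study sample sizes:

    Z_meta = sum_i sqrt(n_i) Z_i / sqrt(sum_i n_i).

Directional tests (burden family) carry the sign of their score
statistic into Z = sign * Phi^{-1}(1 - p/2) and are combined to a
two-sided meta p; direction-free statistics (SKAT, KBAC, VT) use
Z = Phi^{-1}(1 - p) and an upper-tail meta p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["StudySummary", "p_to_z", "combine_z", "DIRECTIONAL_TESTS"]

#: Tests whose score statistic carries a sign usable for directional combination.
DIRECTIONAL_TESTS = {"CMC", "WSS", "single"}

_P_MIN = 1e-15  # numeric safety clamp before the quantile transform
_Z_MAX = float(stats.norm.isf(_P_MIN))


@dataclass
class StudySummary:
    p: float
    direction: int
    n: int
    study_id: str = ""

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.direction not in (-1, 0, 1):
            raise ValueError("direction must be -1, 0 or +1")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")


def p_to_z(summary: StudySummary, directional: bool) -> float:
    """Transform a per-study p-value to a Z score."""
    p = summary.p
    if p <= 0.0:
        raise ValueError("p = 0 is impossible with add-one permutation p-values")
    p = max(p, _P_MIN)
    if directional:
        z = summary.direction * stats.norm.isf(p / 2.0)
    else:
        z = stats.norm.isf(p)
    if not np.isfinite(z):
        # p = 1 exactly: Phi^{-1}(0) is -inf; clamp to the representable extreme
        warnings.warn("p-value at boundary; Z clamped")
        z = -_Z_MAX if z < 0 else _Z_MAX
    return float(np.clip(z, -_Z_MAX, _Z_MAX))


def combine_z(summaries: list[StudySummary], directional: bool) -> tuple[float, float]:
    """Combine per-study Z scores weighted by sqrt(sample size).

    Returns (Z_meta, p_meta) with p_meta two-sided for directional
    statistics and upper-tail otherwise.
    """
    if not summaries:
        raise ValueError("need at least one study")
    z = np.array([p_to_z(s, directional) for s in summaries])
    n = np.array([s.n for s in summaries], dtype=float)
    z_meta = float(np.sqrt(n) @ z / np.sqrt(n.sum()))
    if directional:
        p_meta = float(2.0 * stats.norm.sf(abs(z_meta)))
    else:
        p_meta = float(stats.norm.sf(z_meta))
    return z_meta, min(p_meta, 1.0)
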