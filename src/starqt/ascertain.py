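"""Extreme-tail selection on the primary trait.

Individuals are ascertained when their primary trait falls in a
two-sided tail region (y1 <= lower_cut or y1 >= upper_cut).  The region
is carried forward because the null likelihood must condition on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionRegion", "AscertainedSample", "select_extremes", "region_from_quantiles"]


@dataclass
class SelectionRegion:
    """Two-sided tail region: selected iff y1 <= lower_cut or y1 >= upper_cut."""

    lower_cut: float
    upper_cut: float

    def __post_init__(self):
        if not self.lower_cut < self.upper_cut:
            raise ValueError(
                f"require lower_cut < upper_cut, got ({self.lower_cut}, {self.upper_cut})"
            )

    def contains(self, y1) -> np.ndarray:
        y1 = np.asarray(y1, dtype=float)
        return (y1 <= self.lower_cut) | (y1 >= self.upper_cut)


@dataclass
class AscertainedSample:
    indices: np.ndarray          # positions of selected individuals in the cohort
    A: np.ndarray                # per-cohort-individual ascertainment flag
    region: SelectionRegion
    tail: np.ndarray             # per-selected-individual label: 'low' or 'high'

    @property
    def n_selected(self) -> int:
        return self.indices.size


def select_extremes(y1, n_select: int) -> AscertainedSample:
    """Select the most extreme individuals by rank on the primary trait.

    The ceil(n_select/2) smallest and floor(n_select/2) largest values
    are taken (odd counts favour the lower tail).  Ties at a cut are
    broken by (value, original index), so selection is deterministic
    across platforms.  The stored region cuts are the innermost selected
    value of each tail.
    """
    y1 = np.asarray(y1, dtype=float)
    n = y1.size
    if n_select < 2:
        raise ValueError("n_select must be >= 2")
    if n_select > n:
        raise ValueError(f"n_select ({n_select}) exceeds cohort size ({n})")
    n_low = int(np.ceil(n_select / 2))
    n_high = n_select - n_low
    order = np.lexsort((np.arange(n), y1))  # stable rank by (value, index)
    low_idx = order[:n_low]
    high_idx = order[n - n_high:]
    indices = np.concatenate([low_idx, high_idx])
    A = np.zeros(n, dtype=bool)
    A[indices] = True
    region = SelectionRegion(lower_cut=float(y1[order[n_low - 1]]),
                             upper_cut=float(y1[order[n - n_high]]))
    tail = np.array(["low"] * n_low + ["high"] * n_high)
    return AscertainedSample(indices=indices, A=A, region=region, tail=tail)


def region_from_quantiles(y1, q_low: float, q_high: float) -> SelectionRegion:
    """Selection region with cuts at the empirical q_low / q_high quantiles."""
    if not (0.0 < q_low < q_high < 1.0):
        raise ValueError("require 0 < q_low < q_high < 1")
    y1 = np.asarray(y1, dtype=float)
    lo, hi = np.quantile(y1, [q_low, q_high])
    return SelectionRegion(lower_cut=float(lo), upper_cut=float(hi))
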