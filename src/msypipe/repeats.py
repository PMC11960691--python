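"""Region-wise repeat content and Kimura 2-parameter repeat-age contrast.

Repeat discovery itself is out of scope; the module consumes repeat
intervals annotated with the element-versus-consensus transition (P) and
transversion (Q) proportions, converts them to K2P distances (the standard
repeat-age proxy), measures merged repeat coverage per region, and tests
whether MSY elements are younger than PAR elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RepeatInterval",
    "RegionRepeatSummary",
    "kimura2p",
    "p_q_from_alignment",
    "merge_intervals",
    "region_repeat_fraction",
    "summarize_region",
    "age_contrast",
]


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    family: str
    P: float  # transition proportion vs consensus
    Q: float  # transversion proportion vs consensus

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty repeat interval")


@dataclass
class RegionRepeatSummary:
    region: str
    repeat_fraction: float
    n_elements: int
    kimura: np.ndarray = field(repr=False)

    @property
    def median_kimura(self) -> float:
        return float(np.median(self.kimura)) if len(self.kimura) else float("nan")


def kimura2p(P: float, Q: float) -> float:
    """Kimura 2-parameter distance K = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    P and Q are the observed transition and transversion proportions.
    Raises ValueError naming the offending term outside the model domain.
    """
    if P < 0 or Q < 0:
        raise ValueError(f"negative proportion: P={P}, Q={Q}")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0:
        raise ValueError(f"K2P domain violation: 1-2P-Q = {a:.6g} <= 0")
    if b <= 0:
        raise ValueError(f"K2P domain violation: 1-2Q = {b:.6g} <= 0")
    return -0.5 * math.log(a * math.sqrt(b))


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def p_q_from_alignment(element: str, consensus: str) -> tuple[float, float]:
    """Observed P and Q from a gap-free pairwise element/consensus alignment."""
    if len(element) != len(consensus):
        raise ValueError("element and consensus must be aligned to equal length")
    n = ts = tv = 0
    for a, b in zip(element.upper(), consensus.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    return ts / n, tv / n


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def region_repeat_fraction(
    intervals: Sequence[RepeatInterval] | Sequence[tuple[int, int]],
    region: tuple[int, int],
) -> float:
    """Fraction of a region covered by (merged) repeat intervals."""
    r0, r1 = region
    if r1 <= r0:
        raise ValueError("empty region")
    raw = [
        (iv.start, iv.end) if isinstance(iv, RepeatInterval) else (iv[0], iv[1])
        for iv in intervals
    ]
    covered = 0
    for s, e in merge_intervals(raw):
        covered += max(0, min(e, r1) - max(s, r0))
    return covered / (r1 - r0)


def summarize_region(
    intervals: Sequence[RepeatInterval], region: tuple[int, int], label: str
) -> RegionRepeatSummary:
    """Repeat fraction and per-element K2P values for elements in a region.

    An element is attributed to the region containing its midpoint.
    """
    inside = [
        iv for iv in intervals if region[0] <= (iv.start + iv.end) // 2 < region[1]
    ]
    kim = np.array([kimura2p(iv.P, iv.Q) for iv in inside])
    return RegionRepeatSummary(
        region=label,
        repeat_fraction=region_repeat_fraction(intervals, region),
        n_elements=len(inside),
        kimura=kim,
    )


def age_contrast(
    par_summary: RegionRepeatSummary, msy_summary: RegionRepeatSummary
) -> dict:
    """Two-sided rank test of K2P repeat ages between PAR and MSY.

    Returns the Mann-Whitney U statistic, its p-value, the MSY-PAR median
    difference, and an ``underpowered`` flag when either side has < 5
    elements (in which case the test is not run).
    """
    n_par, n_msy = len(par_summary.kimura), len(msy_summary.kimura)
    out = {
        "n_par": n_par,
        "n_msy": n_msy,
        "median_par": par_summary.median_kimura,
        "median_msy": msy_summary.median_kimura,
        "median_diff": msy_summary.median_kimura - par_summary.median_kimura,
        "underpowered": n_par < 5 or n_msy < 5,
    }
    if out["underpowered"]:
        out["statistic"] = float("nan")
        out["p_value"] = float("nan")
        return out
    if np.array_equal(par_summary.kimura, msy_summary.kimura):
        # identical samples: rank test is degenerate, report p = 1
        out["statistic"] = float(n_par * n_msy / 2)
        out["p_value"] = 1.0
        return out
    res = stats.mannwhitneyu(
        msy_summary.kimura, par_summary.kimura, alternative="two-sided"
    )
    out["statistic"] = float(res.statistic)
    out["p_value"] = float(res.pvalue)
    return out


def element_table(intervals: Sequence[RepeatInterval]) -> pd.DataFrame:
    """Per-element table with K2P values, suitable for plotting landscapes."""
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "family": [iv.family for iv in intervals],
            "P": [iv.P for iv in intervals],
            "Q": [iv.Q for iv in intervals],
            "kimura": [kimura2p(iv.P, iv.Q) for iv in intervals],
        }
    )
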