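"""Reference-scenario evaluation runs.

These helpers execute the pipeline on the default synthetic scenario at a
reduced scale and measure recovery of the planted structure: windowed
divergence levels in the true PAR and MSY segments, the boundary call, and
the distal concentration of male-only RAD-tag hits.  They are used by the
acceptance checks and are convenient for benchmarking parameter changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic
from .config import ScenarioConfig
from .divergence import divergence_profile
from .sexmarkers import (
    build_tag_catalog,
    call_male_only_tags,
    map_tags,
    region_enrichment,
)

__all__ = ["DivergenceRecovery", "RadRecovery", "divergence_recovery", "rad_recovery"]

DEFAULT_SCALE = 0.1  # 2.85 Mb desk-scale chromosome


@dataclass
class DivergenceRecovery:
    seed: int
    scale: float
    chrom_end: int
    boundary_true: int
    changepoint: int
    distal_mean: float  # mean window divergence % inside the true MSY
    proximal_mean: float  # mean window divergence % inside the true PAR
    fold: float
    n_distal_windows: int
    n_proximal_windows: int

    @property
    def changepoint_mb_equiv(self) -> float:
        """Changepoint rescaled to full-genome units (Mb)."""
        return self.changepoint / self.scale / 1e6

    @property
    def distal_length_mb_equiv(self) -> float:
        return (self.chrom_end - self.changepoint) / self.scale / 1e6


@dataclass
class RadRecovery:
    seed: int
    n_male_only: int
    n_hits: int
    pct_distal16: float  # % of best hits in the distal 16% of the chromosome
    binomial_p: float


def divergence_recovery(seed: int, scale: float = DEFAULT_SCALE) -> DivergenceRecovery:
    """Run the X-Y scan on the default scenario and measure recovery.

    Windows are 10 kb scaled by ``scale`` (1 kb at the default 0.1);
    segment means are taken over windows lying fully inside the true
    planted PAR/MSY intervals.
    """
    cfg = ScenarioConfig(scale=scale, seed=seed)
    x, y, truth = synthetic.simulate_xy_pair(cfg)
    _, windows, boundary = divergence_profile(x, y, window_bp=cfg.bp(10_000))
    msy0, msy1 = truth.msy_interval
    par0, par1 = truth.par_interval
    distal = [w.divergence_pct for w in windows if w.t_start >= msy0 and w.t_end <= msy1]
    proximal = [w.divergence_pct for w in windows if w.t_start >= par0 and w.t_end <= par1]
    return DivergenceRecovery(
        seed=seed,
        scale=scale,
        chrom_end=len(y),
        boundary_true=truth.boundary_y,
        changepoint=boundary.changepoint_bp,
        distal_mean=float(np.mean(distal)),
        proximal_mean=float(np.mean(proximal)),
        fold=boundary.fold,
        n_distal_windows=len(distal),
        n_proximal_windows=len(proximal),
    )


def rad_recovery(seed: int, scale: float = DEFAULT_SCALE) -> RadRecovery:
    """Run the RAD sex-marker route on the default scenario.

    Male-only tags are called at min_males = half the males and zero
    female occurrences, mapped back to Y (E <= 1e-40), and the fraction of
    best hits inside the distal 16% of the chromosome is measured.
    """
    cfg = ScenarioConfig(scale=scale, seed=seed)
    _, y, truth = synthetic.simulate_xy_pair(cfg)
    rad = synthetic.simulate_rad_individuals(cfg, y, truth)
    catalog = build_tag_catalog(rad.read_counts(), rad.sex.to_dict())
    male_only = call_male_only_tags(
        catalog, min_males=max(1, cfg.n_males // 2), max_females=0
    )
    hits = map_tags(
        [(tid, catalog.sequence_of(tid)) for tid in male_only], y, evalue_max=1e-40
    )
    frac, p = region_enrichment(hits, (int(0.84 * len(y)), len(y)), len(y))
    return RadRecovery(
        seed=seed,
        n_male_only=len(male_only),
        n_hits=len(hits),
        pct_distal16=100.0 * frac,
        binomial_p=p,
    )
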