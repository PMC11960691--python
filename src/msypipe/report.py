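"""Evidence integration: a consensus MSY call with a machine-readable report.

The boundary from the X-Y divergence scan, the positions of male-only
RAD-tag hits, the pooled-sex SNP windows and the repeat summaries are
combined into one report.  The consensus interval is conservative: the
intersection of the divergence MSY with the smallest interval holding the
upper quantile mass of male-only hit positions (different marker sets can
delimit different proximal borders, so the report keeps every per-evidence
interval alongside the consensus).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import ScenarioConfig
from .divergence import BoundaryCall, windows_frame
from .poolsex import SexSnpWindow, pool_windows_frame
from .repeats import RegionRepeatSummary
from .sexmarkers import TagHit

logger = logging.getLogger(__name__)

__all__ = ["EvidenceBundle", "MsyReport", "integrate_evidence", "run_pipeline"]


@dataclass
class EvidenceBundle:
    boundary: BoundaryCall
    chrom_length: int
    rad_hits: Sequence[TagHit] = ()
    rad_enrichment: tuple[float, float] | None = None  # (fraction, p)
    pool_windows: Sequence[SexSnpWindow] = ()
    repeat_par: RegionRepeatSummary | None = None
    repeat_msy: RegionRepeatSummary | None = None
    repeat_age: dict | None = None


@dataclass
class MsyReport:
    consensus: tuple[int, int] | None
    intervals: dict[str, tuple[int, int] | None]
    support: dict[str, str]  # evidence -> supporting | neutral | conflicting
    chrom_length: int
    details: dict = field(default_factory=dict)
    config: dict | None = None
    seed: int | None = None
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "chrom_length": self.chrom_length,
            "consensus": list(self.consensus) if self.consensus else None,
            "intervals": {
                k: (list(v) if v else None) for k, v in self.intervals.items()
            },
            "support": dict(self.support),
            "details": self.details,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def _intersect(a: tuple[int, int] | None, b: tuple[int, int] | None):
    if a is None or b is None:
        return None
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if hi > lo else None


def _overlap_flag(interval, reference) -> str:
    if interval is None:
        return "neutral"
    inter = _intersect(interval, reference)
    if inter is None:
        return "conflicting"
    smaller = min(interval[1] - interval[0], reference[1] - reference[0])
    return "supporting" if (inter[1] - inter[0]) >= 0.5 * smaller else "conflicting"


def _smallest_mass_interval(positions: np.ndarray, quantile: float):
    """Smallest interval containing at least `quantile` of the positions."""
    pos = np.sort(np.asarray(positions))
    n = len(pos)
    if n == 0:
        return None
    m = max(1, math.ceil(quantile * n))
    widths = pos[m - 1 :] - pos[: n - m + 1]
    i = int(np.argmin(widths))
    return (int(pos[i]), int(pos[i + m - 1]) + 1)


def integrate_evidence(bundle: EvidenceBundle, rad_quantile: float = 0.9) -> MsyReport:
    """Combine divergence, RAD, pool and repeat evidence into an MSY call.

    The divergence MSY is [changepoint, chrom_end); the RAD interval is the
    smallest interval containing the upper ``rad_quantile`` mass of
    male-only hit positions; the consensus is their intersection (the
    divergence interval alone when no male-only tags exist).
    """
    div_iv = None if bundle.boundary.no_transition else tuple(bundle.boundary.msy_interval)
    intervals: dict = {"divergence": div_iv}
    support: dict = {
        "divergence": "neutral" if div_iv is None else "supporting"
    }
    details: dict = {
        "boundary": {
            "changepoint_bp": bundle.boundary.changepoint_bp,
            "mean_before": bundle.boundary.mean_before,
            "mean_after": bundle.boundary.mean_after,
            "fold": bundle.boundary.fold,
            "no_transition": bundle.boundary.no_transition,
        }
    }

    rad_pos = np.array([h.t_position for h in bundle.rad_hits], dtype=np.int64)
    rad_iv = _smallest_mass_interval(rad_pos, rad_quantile) if len(rad_pos) else None
    intervals["rad"] = rad_iv
    if bundle.rad_enrichment is not None:
        details["rad_enrichment"] = {
            "fraction_in_region": bundle.rad_enrichment[0],
            "binomial_p": bundle.rad_enrichment[1],
        }
    details["rad_n_hits"] = int(len(rad_pos))

    pool_iv = None
    usable = [w for w in bundle.pool_windows if "low_coverage" not in w.flags]
    counts = np.array([w.n_sex_snps for w in usable])
    if len(usable) and counts.sum() > 0:
        med = float(np.median(counts))
        hot = [w for w, c in zip(usable, counts) if c > max(2 * med, 1)]
        if hot:
            pool_iv = (min(w.start for w in hot), max(w.end for w in hot))
    intervals["pool"] = pool_iv

    if div_iv is not None and rad_iv is not None:
        consensus = _intersect(div_iv, rad_iv)
        if consensus is None:
            consensus = div_iv
            support["rad"] = "conflicting"
        else:
            support["rad"] = _overlap_flag(rad_iv, div_iv)
    elif div_iv is not None:
        consensus = div_iv
        support["rad"] = "neutral"
    else:
        consensus = rad_iv
        support["rad"] = "neutral" if rad_iv is None else "supporting"

    reference = consensus or div_iv
    support["pool"] = (
        _overlap_flag(pool_iv, reference) if reference is not None else "neutral"
    )

    if bundle.repeat_par is not None and bundle.repeat_msy is not None:
        enriched = bundle.repeat_msy.repeat_fraction > bundle.repeat_par.repeat_fraction
        support["repeats"] = "supporting" if enriched else "neutral"
        details["repeats"] = {
            "fraction_par": bundle.repeat_par.repeat_fraction,
            "fraction_msy": bundle.repeat_msy.repeat_fraction,
            "age_contrast": bundle.repeat_age,
        }
    else:
        support["repeats"] = "neutral"

    return MsyReport(
        consensus=consensus,
        intervals=intervals,
        support=support,
        chrom_length=bundle.chrom_length,
        details=details,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline on a synthetic scenario


def run_pipeline(config: ScenarioConfig, outdir) -> MsyReport:
    """Simulate a scenario, run every stage, write all outputs, and report.

    Stage outputs (FASTA, TSV, BED, GFF3, JSON) carry a provenance header
    with version, configuration hash and seed.  Reruns with the same
    configuration are byte-identical.
    """
    from . import io as mio
    from . import synthetic
    from .divergence import divergence_profile
    from .genes import merge_annotation, write_gff3
    from .poolsex import call_sex_specific_snps, window_sex_snp_scan, write_sync
    from .repeats import age_contrast, summarize_region
    from .sexmarkers import (
        build_tag_catalog,
        call_male_only_tags,
        map_tags,
        region_enrichment,
        tile_distribution,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/6: simulating X-Y pair (length %d bp)", config.length)
    x, y, truth = synthetic.simulate_xy_pair(config)
    mio.write_fasta(outdir / "xy.fasta", {"X": x, "Y": y})
    mio.write_bed(
        outdir / "truth_regions.bed",
        [("Y", *truth.par_interval, "PAR"), ("Y", *truth.msy_interval, "MSY")],
        config,
    )

    logger.info("stage 2/6: X-Y divergence scan")
    window_bp = max(config.bp(10_000), 100)
    netted, windows, boundary = divergence_profile(x, y, window_bp=window_bp)
    mio.write_tsv(outdir / "divergence_windows.tsv", windows_frame(windows), config)
    mio.write_bed(
        outdir / "msy_divergence.bed",
        [("Y", *boundary.msy_interval, "MSY_divergence")],
        config,
        extra=f"fold={boundary.fold:.4f}",
    )
    logger.info(
        "  boundary at %d bp, fold %.2f (%d windows)",
        boundary.changepoint_bp, boundary.fold, boundary.n_windows_used,
    )

    logger.info("stage 3/6: RAD-tag sex markers")
    rad = synthetic.simulate_rad_individuals(config, y, truth)
    catalog = build_tag_catalog(rad.read_counts(), rad.sex.to_dict())
    tile = tile_distribution(catalog)
    mio.write_tsv(
        outdir / "tile_table.tsv", tile.to_frame().reset_index(), config
    )
    male_only = call_male_only_tags(
        catalog, min_males=max(1, config.n_males // 2), max_females=0
    )
    tag_pairs = [(tid, catalog.sequence_of(tid)) for tid in male_only]
    hits = map_tags(tag_pairs, y)
    distal = (int(0.84 * len(y)), len(y))
    enrichment = region_enrichment(hits, distal, len(y))
    mio.write_bed(
        outdir / "male_only_hits.bed",
        [("Y", h.t_position, h.t_position + config.tag_len, h.tag_id) for h in hits],
        config,
    )
    logger.info(
        "  %d male-only tags, %d mapped, %.1f%% in distal 16%%",
        len(male_only), len(hits), 100 * enrichment[0],
    )

    logger.info("stage 4/6: pooled-sex SNP scan")
    pool = synthetic.simulate_pool_counts(config, x, y, truth)
    write_sync(pool, outdir / "pool_counts.sync")
    sites, qc = call_sex_specific_snps(pool)
    pool_windows = window_sex_snp_scan(
        sites, pool, window_bp=max(config.bp(50_000), 500), chrom_length=truth.x_length
    )
    mio.write_tsv(
        outdir / "pool_windows.tsv",
        pool_windows_frame(pool_windows),
        config,
        extra=f"min_depth={qc['min_depth']} het_band={qc['het_band']} max_other={qc['max_other']}",
    )
    logger.info("  %d sex-specific sites (%d low-depth skipped)", len(sites), qc["n_low_depth_skipped"])

    logger.info("stage 5/6: gene evidence and repeats")
    evidence = synthetic.simulate_gene_evidence(config)
    merged = merge_annotation(
        evidence.homology, evidence.abinitio,
        evidence.transcript_cover, evidence.junctions,
    )
    write_gff3(merged.final_models, outdir / "annotation.gff3", merged.provenance)
    repeats = synthetic.simulate_repeats(config, truth)
    par_sum = summarize_region(repeats, truth.par_interval, "PAR")
    msy_sum = summarize_region(repeats, truth.msy_interval, "MSY")
    age = age_contrast(par_sum, msy_sum)
    logger.info(
        "  %d final gene models; repeat fraction PAR %.3f vs MSY %.3f",
        len(merged.final_models), par_sum.repeat_fraction, msy_sum.repeat_fraction,
    )

    logger.info("stage 6/6: evidence integration")
    bundle = EvidenceBundle(
        boundary=boundary,
        chrom_length=len(y),
        rad_hits=hits,
        rad_enrichment=enrichment,
        pool_windows=pool_windows,
        repeat_par=par_sum,
        repeat_msy=msy_sum,
        repeat_age=age,
    )
    report = integrate_evidence(bundle)
    report.config = config.to_dict()
    report.seed = config.seed
    (outdir / "msy_report.json").write_text(report.to_json() + "\n")

    rows = [
        ("consensus", *(report.consensus or ("NA", "NA"))),
        *[
            (name, *(iv or ("NA", "NA")))
            for name, iv in sorted(report.intervals.items())
        ],
    ]
    mio.write_tsv(
        outdir / "msy_report.tsv",
        pd.DataFrame(rows, columns=["evidence", "start", "end"]),
        config,
    )
    if report.consensus:
        mio.write_bed(
            outdir / "msy_consensus.bed",
            [("Y", *report.consensus, "MSY_consensus")],
            config,
        )
    return report
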