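"""Scenario configuration for the synthetic sex-chromosome generator.

The default values describe the "reference scenario": a 28.5 Mb Y
chromosome whose proximal 23.5 Mb recombine with the X (PAR, ~1% windowed
X-Y difference) and whose distal 5 Mb are male specific (MSY, ~6%
difference, i.e. about fivefold higher).  All base-pair quantities are
multiplied by ``scale`` when sequences are generated, so tests and the
acceptance runs can exercise the full pipeline on a 2.85 Mb chromosome
(``scale=0.1``) without changing any rate-type parameter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["ScenarioConfig"]


@dataclass(frozen=True)
class ScenarioConfig:
    # chromosome geometry (full-scale bp; multiplied by `scale` on use)
    chrom_length_bp: int = 28_500_000
    boundary_bp: int = 23_500_000
    telomere_bp: int = 3_000

    # X->Y edit process per region.  Expected windowed difference is
    # roughly sub_rate + indel_rate * indel_mean_len, i.e. ~1% in the PAR
    # and ~6% in the MSY with the defaults below.
    sub_rate_par: float = 0.008
    sub_rate_msy: float = 0.048
    indel_rate_par: float = 0.0005
    indel_rate_msy: float = 0.003
    indel_mean_len: float = 4.0

    # RAD-tag cohort: two sexes, tag loci sampled on Y; male-limited loci
    # placed 70% distal of the enrichment cutoff, remainder in the
    # proximal band, emulating the observed distal concentration.
    n_males: int = 30
    n_females: int = 30
    n_tag_loci: int = 1_000
    n_male_only_loci: int = 200
    male_only_fraction_distal: float = 0.70
    tag_len: int = 95
    tag_mean_depth: float = 20.0
    tag_dropout: float = 0.10
    distal_cutoff_bp: int = 24_000_000
    proximal_band_bp: tuple[int, int] = (20_000_000, 23_500_000)

    # pooled-sex sequencing (30 XY males vs 30 XX females)
    pool_depth: float = 50.0
    pool_site_spacing_bp: int = 1_000
    pool_mask_start_bp: int = 26_000_000  # terminal mapping-failure mask
    pool_mask_depth_factor: float = 0.05

    # trio read binning scenario
    trio_hap_len_bp: int = 2_000_000
    trio_divergence: float = 0.02
    trio_read_error: float = 0.01
    n_trio_reads: int = 1_000
    trio_read_mean_len: int = 8_000
    trio_read_sigma: float = 0.6

    # gene-evidence scenario
    n_genes: int = 60
    gene_corrupt_prob: float = 0.30
    gene_abinitio_only_prob: float = 0.15
    gene_support_fraction: float = 1.0

    # repeat landscape
    repeat_density_par: float = 0.35
    repeat_density_msy: float = 0.55
    repeat_age_par: float = 0.20
    repeat_age_msy: float = 0.15
    repeat_age_sd: float = 0.05
    repeat_mean_len: int = 350

    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.boundary_bp < self.chrom_length_bp:
            raise ValueError("boundary_bp must lie strictly inside the chromosome")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        for name in (
            "sub_rate_par",
            "sub_rate_msy",
            "indel_rate_par",
            "indel_rate_msy",
            "tag_dropout",
        ):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        # alignment identifiability: reject edit processes expected to
        # diverge the two sequences by more than 50%
        for region in ("par", "msy"):
            sub = getattr(self, f"sub_rate_{region}")
            ind = getattr(self, f"indel_rate_{region}")
            if sub + ind * self.indel_mean_len > 0.5:
                raise ValueError(
                    f"{region} rates imply >50% expected divergence; "
                    "the X-Y alignment would not be identifiable"
                )
        if self.indel_mean_len < 1:
            raise ValueError("indel_mean_len must be >= 1")
        if self.n_male_only_loci > self.n_tag_loci:
            raise ValueError("n_male_only_loci cannot exceed n_tag_loci")
        if not 0 <= self.male_only_fraction_distal <= 1:
            raise ValueError("male_only_fraction_distal must be in [0, 1]")

    # -- scaled geometry -------------------------------------------------

    def bp(self, full_scale_bp: float) -> int:
        """Map a full-scale bp quantity into the scaled coordinate system."""
        return int(round(full_scale_bp * self.scale))

    @property
    def length(self) -> int:
        return self.bp(self.chrom_length_bp)

    @property
    def boundary(self) -> int:
        return self.bp(self.boundary_bp)

    # -- randomness ------------------------------------------------------

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator for one pipeline component.

        Each named stream is seeded from ``(seed, crc32(stream))`` so that
        regenerating e.g. the RAD cohort does not perturb the X-Y pair.
        """
        return np.random.default_rng(
            [int(self.seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())]
        )

    # -- provenance ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proximal_band_bp"] = list(d["proximal_band_bp"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)
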