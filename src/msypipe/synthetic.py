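"""Seeded synthetic sex-chromosome scenario with planted ground truth.

Every input the pipeline consumes can be generated here: an X/Y sequence
pair whose Y was derived from the X by region-specific substitution and
indel processes (low-divergence proximal PAR, sharply elevated distal MSY,
telomere-like termini), RAD-tag cohorts with male-limited loci concentrated
distally, pooled-sex allele-count tables, trio long reads with known
parental origin, gene models from several evidence classes with partial
transcript support, and repeat annotations whose MSY elements are younger.

All coordinates are 0-based half-open.  Randomness comes from named
sub-streams of one seed (see :meth:`msypipe.config.ScenarioConfig.rng`), so
each component is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .genes import GeneModel
from .repeats import RepeatInterval

__all__ = [
    "TruthSet",
    "RadDataset",
    "TrioDataset",
    "GeneEvidenceSet",
    "simulate_xy_pair",
    "simulate_rad_individuals",
    "simulate_pool_counts",
    "simulate_trio_reads",
    "simulate_gene_evidence",
    "simulate_repeats",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TELOMERE_UNIT = "TTAGGG"


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass
class IndelRecord:
    kind: str  # "ins" | "del"
    x_start: int
    x_end: int  # deleted X span; for insertions x_start == x_end
    y_start: int
    y_end: int  # inserted Y span; for deletions y_start == y_end

    @property
    def length(self) -> int:
        return max(self.x_end - self.x_start, self.y_end - self.y_start)


@dataclass
class TruthSet:
    """Planted ground truth for one scenario."""

    chrom: str
    x_length: int
    y_length: int
    boundary_x: int  # PAR/MSY transition on X coordinates
    boundary_y: int  # same transition mapped onto Y coordinates
    snp_x: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    snp_y: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    indels: list[IndelRecord] = field(default_factory=list)
    telomere_intervals: list[tuple[int, int]] = field(default_factory=list)
    male_only_tag_ids: set[str] = field(default_factory=set)
    true_gene_models: list[GeneModel] = field(default_factory=list)
    repeat_intervals: list[RepeatInterval] = field(default_factory=list)

    @property
    def par_interval(self) -> tuple[int, int]:
        return (0, self.boundary_y)

    @property
    def msy_interval(self) -> tuple[int, int]:
        return (self.boundary_y, self.y_length)


# ---------------------------------------------------------------------------
# X/Y pair


def _region_events(rng, x0, x1, sub_rate, indel_rate):
    n = x1 - x0
    subs = x0 + np.flatnonzero(rng.random(n) < sub_rate) if sub_rate > 0 else np.empty(0, int)
    inds = x0 + np.flatnonzero(rng.random(n) < indel_rate) if indel_rate > 0 else np.empty(0, int)
    return np.asarray(subs, dtype=np.int64), np.asarray(inds, dtype=np.int64)


def simulate_xy_pair(config: ScenarioConfig) -> tuple[str, str, TruthSet]:
    """Generate an (X, Y) chromosome pair and the planted edit truth.

    Y is derived from X by substitutions and geometric-length indels at
    region-specific rates (PAR proximal of the boundary, MSY distal).
    Telomere-like (TTAGGG)n tracts overwrite the terminal ``telomere_bp``
    bases of both chromosomes; planted edits falling inside an overwritten
    span are removed from the truth set.
    """
    rng = config.rng("xy_pair")
    L = config.length
    B = config.boundary
    x = rng.integers(0, 4, L, dtype=np.uint8)

    # event positions per region
    sub_par, ind_par = _region_events(rng, 0, B, config.sub_rate_par, config.indel_rate_par)
    sub_msy, ind_msy = _region_events(rng, B, L, config.sub_rate_msy, config.indel_rate_msy)
    subs = np.concatenate([sub_par, sub_msy])
    inds = np.concatenate([ind_par, ind_msy])
    sub_offsets = rng.integers(1, 4, subs.size, dtype=np.uint8)
    ind_is_ins = rng.random(inds.size) < 0.5
    ind_lens = rng.geometric(1.0 / config.indel_mean_len, inds.size) if inds.size else np.empty(0, int)

    # merge into one left-to-right event stream; an indel starting at the
    # same base as a substitution takes precedence
    events: list[tuple[int, int, int, int]] = []  # (x, priority, kind, payload)
    for pos, off in zip(subs, sub_offsets):
        events.append((int(pos), 1, 0, int(off)))
    for pos, is_ins, ln in zip(inds, ind_is_ins, ind_lens):
        events.append((int(pos), 0, 1 if is_ins else 2, int(ln)))
    events.sort()

    segments: list[np.ndarray] = []
    snp_x: list[int] = []
    snp_y: list[int] = []
    indels: list[IndelRecord] = []
    xptr = 0
    ypos = 0
    last_x = -1
    for xev, _, kind, payload in events:
        if xev < xptr or xev == last_x:
            continue  # swallowed by a deletion, or duplicate event position
        last_x = xev
        if xev > xptr:
            segments.append(x[xptr:xev])
            ypos += xev - xptr
        if kind == 0:  # substitution
            segments.append(np.array([(x[xev] + payload) % 4], dtype=np.uint8))
            snp_x.append(xev)
            snp_y.append(ypos)
            ypos += 1
            xptr = xev + 1
        elif kind == 1:  # insertion after this base
            segments.append(x[xev : xev + 1])
            ypos += 1
            ins = rng.integers(0, 4, payload, dtype=np.uint8)
            segments.append(ins)
            indels.append(IndelRecord("ins", xev + 1, xev + 1, ypos, ypos + payload))
            ypos += payload
            xptr = xev + 1
        else:  # deletion of payload bases starting here
            x_end = min(xev + payload, L)
            indels.append(IndelRecord("del", xev, x_end, ypos, ypos))
            xptr = x_end
    if xptr < L:
        segments.append(x[xptr:])
        ypos += L - xptr
    y = np.concatenate(segments) if segments else np.empty(0, dtype=np.uint8)
    assert len(y) == ypos

    # Y coordinate of the PAR/MSY boundary
    ins_before = sum(r.y_end - r.y_start for r in indels if r.x_start <= B and r.kind == "ins")
    del_before = sum(min(r.x_end, B) - r.x_start for r in indels if r.kind == "del" and r.x_start < B)
    boundary_y = B + ins_before - del_before

    truth = TruthSet(
        chrom="Y",
        x_length=L,
        y_length=len(y),
        boundary_x=B,
        boundary_y=boundary_y,
        snp_x=np.asarray(snp_x, dtype=np.int64),
        snp_y=np.asarray(snp_y, dtype=np.int64),
        indels=indels,
    )

    # telomere-like termini on both chromosomes
    tel = 6 * (config.bp(config.telomere_bp) // 6)
    if tel > 0 and len(y) > 2 * tel and L > 2 * tel:
        unit = np.frombuffer(_TELOMERE_UNIT.encode(), dtype=np.uint8)
        codes = np.array([{65: 0, 67: 1, 71: 2, 84: 3}[b] for b in unit], dtype=np.uint8)
        tract = np.tile(codes, tel // 6)
        for arr in (x, y):
            arr[:tel] = tract
            arr[-tel:] = tract
        spans = [(0, tel), (len(y) - tel, len(y))]
        truth.telomere_intervals = spans

        def _in_tel(pos):
            return any(s <= pos < e for s, e in spans)

        keep = np.array([not _in_tel(p) for p in truth.snp_y], dtype=bool)
        truth.snp_x = truth.snp_x[keep]
        truth.snp_y = truth.snp_y[keep]
        truth.indels = [
            r
            for r in truth.indels
            if not (_in_tel(r.y_start) or _in_tel(max(r.y_start, r.y_end - 1)))
        ]

    return _codes_to_str(x), _codes_to_str(y), truth


# ---------------------------------------------------------------------------
# RAD-tag cohort


@dataclass
class RadDataset:
    tags: pd.DataFrame  # tag_id, sequence, position, male_limited
    counts: pd.DataFrame  # tags x individuals depth matrix
    sex: pd.Series  # individual -> "M" | "F"

    def read_counts(self) -> dict[str, dict[str, int]]:
        """Per-individual {tag sequence: read count} (catalog-builder input)."""
        seq_of = dict(zip(self.tags["tag_id"], self.tags["sequence"]))
        out: dict[str, dict[str, int]] = {}
        for ind in self.counts.columns:
            col = self.counts[ind]
            out[ind] = {
                seq_of[tid]: int(c) for tid, c in col.items() if c > 0
            }
        return out


def _draw_positions(rng, n, lo, hi, tag_len, forbidden, used_positions):
    """Distinct tag start positions in [lo, hi) avoiding forbidden spans."""
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 100 * n + 1000:
            raise RuntimeError("could not place tag loci; region too small")
        p = int(rng.integers(lo, max(lo + 1, hi - tag_len)))
        if p in used_positions:
            continue
        if any(s - tag_len < p < e for s, e in forbidden):
            continue
        used_positions.add(p)
        out.append(p)
    return out


def simulate_rad_individuals(
    config: ScenarioConfig, y_sequence: str, truth: TruthSet
) -> RadDataset:
    """RAD-tag depth matrix over a male/female cohort.

    Tag loci are substrings of Y.  Male-limited loci occur with nonzero
    depth only in males; ``male_only_fraction_distal`` of them are placed
    distal of the enrichment cutoff, the remainder in the proximal band.
    Shared loci occur in both sexes.  Per-individual dropout zeroes a
    locus with probability ``tag_dropout``.
    """
    if config.n_males < 1 or config.n_females < 1:
        raise ValueError("need at least one individual of each sex")
    if config.n_tag_loci < 1:
        raise ValueError("need at least one tag locus")
    rng = config.rng("rad")
    ylen = len(y_sequence)
    tlen = config.tag_len
    forbidden = list(truth.telomere_intervals)
    used: set[int] = set()

    n_mo = config.n_male_only_loci
    n_shared = config.n_tag_loci - n_mo
    shared_pos = _draw_positions(rng, n_shared, 0, ylen, tlen, forbidden, used)

    distal_lo = config.bp(config.distal_cutoff_bp)
    band_lo = config.bp(config.proximal_band_bp[0])
    band_hi = config.bp(config.proximal_band_bp[1])
    is_distal = rng.random(n_mo) < config.male_only_fraction_distal
    mo_pos = []
    for d in is_distal:
        lo, hi = (distal_lo, ylen) if d else (band_lo, band_hi)
        mo_pos.extend(_draw_positions(rng, 1, lo, hi, tlen, forbidden, used))

    rows = []
    for i, p in enumerate(shared_pos):
        rows.append((f"tag{i:05d}", y_sequence[p : p + tlen], p, False))
    for j, p in enumerate(mo_pos):
        rows.append((f"tag{n_shared + j:05d}", y_sequence[p : p + tlen], p, True))
    tags = pd.DataFrame(rows, columns=["tag_id", "sequence", "position", "male_limited"])

    males = [f"m{i + 1:02d}" for i in range(config.n_males)]
    females = [f"f{i + 1:02d}" for i in range(config.n_females)]
    inds = males + females
    sex = pd.Series(["M"] * len(males) + ["F"] * len(females), index=inds)

    depth = rng.poisson(config.tag_mean_depth, size=(len(tags), len(inds)))
    if config.tag_dropout > 0:
        depth[rng.random(depth.shape) < config.tag_dropout] = 0
    # male-limited loci never appear in females
    mo_mask = tags["male_limited"].to_numpy()
    depth[np.ix_(mo_mask, np.arange(len(males), len(inds)))] = 0
    counts = pd.DataFrame(depth, index=tags["tag_id"], columns=inds)

    truth.male_only_tag_ids = set(tags.loc[tags["male_limited"], "tag_id"])
    return RadDataset(tags=tags, counts=counts, sex=sex)


# ---------------------------------------------------------------------------
# pooled-sex allele counts


def simulate_pool_counts(
    config: ScenarioConfig, x_sequence: str, y_sequence: str, truth: TruthSet
) -> pd.DataFrame:
    """Per-site allele counts for an XY-male and an XX-female pool.

    Sites on the X (reference) comprise every planted SNP plus a regular
    grid of monomorphic sites carrying coverage information.  The female
    pool draws only reference (X) alleles; the male pool carries the
    Y-specific allele at expected frequency 0.5.  Depths are Poisson.
    Mapping failure against the highly diverged terminal region is
    emulated by scaling depth by ``pool_mask_depth_factor`` distal of
    ``pool_mask_start_bp``.
    """
    if config.pool_depth <= 0:
        raise ValueError("pool_depth must be positive")
    rng = config.rng("pool")
    L = truth.x_length
    spacing = max(1, config.bp(config.pool_site_spacing_bp))
    grid = np.arange(0, L, spacing, dtype=np.int64)
    snp_pos = truth.snp_x
    snp_set = set(int(p) for p in snp_pos)
    grid = grid[[int(g) not in snp_set for g in grid]]

    pos = np.concatenate([snp_pos, grid])
    is_snp = np.concatenate([np.ones(len(snp_pos), bool), np.zeros(len(grid), bool)])
    order = np.argsort(pos, kind="stable")
    pos, is_snp = pos[order], is_snp[order]

    snp_alt = {int(px): y_sequence[int(py)] for px, py in zip(truth.snp_x, truth.snp_y)}

    mask_start = config.bp(config.pool_mask_start_bp)
    mean_depth = np.full(len(pos), float(config.pool_depth))
    mean_depth[pos >= mask_start] *= config.pool_mask_depth_factor

    depth_m = rng.poisson(mean_depth)
    depth_f = rng.poisson(mean_depth)
    alt_m = np.where(is_snp, rng.binomial(depth_m, 0.5), 0)

    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m_counts = np.zeros((len(pos), 4), dtype=np.int64)
    f_counts = np.zeros((len(pos), 4), dtype=np.int64)
    refs = []
    for i, p in enumerate(pos):
        ref = x_sequence[int(p)]
        refs.append(ref)
        ri = base_idx[ref]
        m_counts[i, ri] = depth_m[i] - alt_m[i]
        f_counts[i, ri] = depth_f[i]
        if is_snp[i] and alt_m[i] > 0:
            m_counts[i, base_idx[snp_alt[int(p)]]] += alt_m[i]

    return pd.DataFrame(
        {
            "chrom": "X",
            "pos": pos + 1,  # 1-based, sync convention
            "ref": refs,
            "m_A": m_counts[:, 0],
            "m_C": m_counts[:, 1],
            "m_G": m_counts[:, 2],
            "m_T": m_counts[:, 3],
            "f_A": f_counts[:, 0],
            "f_C": f_counts[:, 1],
            "f_G": f_counts[:, 2],
            "f_T": f_counts[:, 3],
        }
    )


# ---------------------------------------------------------------------------
# trio long reads


@dataclass
class TrioDataset:
    parentA: str
    parentB: str
    reads: list[tuple[str, str, str]]  # (read_id, sequence, true origin "A"|"B")


def simulate_trio_reads(config: ScenarioConfig) -> TrioDataset:
    """Child long reads of known parental origin.

    Two parental haplotypes differ by ``trio_divergence`` substitutions;
    child reads are sampled from either haplotype with lognormal lengths
    and per-base sequencing error ``trio_read_error`` (substitutions only;
    quality realism is out of scope).
    """
    rng = config.rng("trio")
    hap_len = config.bp(config.trio_hap_len_bp)
    a = rng.integers(0, 4, hap_len, dtype=np.uint8)
    b = a.copy()
    n_mut = rng.binomial(hap_len, config.trio_divergence)
    mut_pos = rng.choice(hap_len, size=n_mut, replace=False)
    b[mut_pos] = (b[mut_pos] + rng.integers(1, 4, n_mut, dtype=np.uint8)) % 4

    mu = np.log(config.trio_read_mean_len) - config.trio_read_sigma**2 / 2
    lengths = np.clip(
        rng.lognormal(mu, config.trio_read_sigma, config.n_trio_reads).astype(int),
        300,
        hap_len,
    )
    origins = rng.random(config.n_trio_reads) < 0.5
    reads = []
    for i in range(config.n_trio_reads):
        hap = a if origins[i] else b
        ln = int(lengths[i])
        start = int(rng.integers(0, hap_len - ln + 1))
        codes = hap[start : start + ln].copy()
        if config.trio_read_error > 0:
            n_err = rng.binomial(ln, config.trio_read_error)
            if n_err:
                epos = rng.choice(ln, size=n_err, replace=False)
                codes[epos] = (codes[epos] + rng.integers(1, 4, n_err, dtype=np.uint8)) % 4
        reads.append((f"read{i:05d}", _codes_to_str(codes), "A" if origins[i] else "B"))
    return TrioDataset(parentA=_codes_to_str(a), parentB=_codes_to_str(b), reads=reads)


# ---------------------------------------------------------------------------
# gene evidence


@dataclass
class GeneEvidenceSet:
    homology: list[GeneModel]
    abinitio: list[GeneModel]
    transcript_cover: list[tuple[int, int]]
    junctions: list[tuple[int, int, str]]
    truth_models: list[GeneModel]


def _make_exons(rng, start: int) -> tuple[tuple[int, int], ...]:
    n_ex = int(rng.integers(1, 9))
    exons = []
    pos = start
    for i in range(n_ex):
        ln = int(rng.integers(100, 401))
        exons.append((pos, pos + ln))
        pos += ln + int(rng.integers(200, 2001))
    return tuple(exons)


def _extend_terminal(model: GeneModel, side: str, factor: int) -> GeneModel:
    """Shift a terminal exon's outer edge outward by factor * exon length."""
    exons = list(model.exons)
    if side == "left":
        s, e = exons[0]
        exons[0] = (max(0, s - factor * (e - s)), e)
    else:
        s, e = exons[-1]
        exons[-1] = (s, e + factor * (e - s))
    from dataclasses import replace

    return replace(model, exons=tuple(exons))


def simulate_gene_evidence(config: ScenarioConfig) -> GeneEvidenceSet:
    """Gene models from three evidence classes with planted truth.

    For each true gene either (a) only a fully supported ab initio model
    exists (recruitment case), or (b) homology models exist, possibly with
    one terminal exon corrupted in the best-supported model while an
    eliminated cluster member carries the correct exon (rescue case).
    Transcript support covers ``gene_support_fraction`` of each true
    exon's bases; with faithful support (fraction 1) the merged annotation
    must equal the planted truth exactly.
    """
    rng = config.rng("genes")
    truth_models: list[GeneModel] = []
    homology: list[GeneModel] = []
    abinitio: list[GeneModel] = []
    cover: list[tuple[int, int]] = []
    junctions: list[tuple[int, int, str]] = []

    pos = 10_000
    for g in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _make_exons(rng, pos)
        truth = GeneModel(
            model_id=f"g{g:03d}", source="homology", chrom="Y", strand=strand, exons=exons
        )
        truth_models.append(truth)
        frac = config.gene_support_fraction
        for s, e in exons:
            cover.append((s, s + max(1, int(round(frac * (e - s))))))
        junctions.extend((s, e, strand) for s, e in truth.introns)

        u = rng.random()
        if u < config.gene_abinitio_only_prob:
            abinitio.append(
                GeneModel(f"g{g:03d}_ab", "abinitio", "Y", strand, exons)
            )
        elif u < config.gene_abinitio_only_prob + config.gene_corrupt_prob and len(exons) >= 2:
            bad_side = "left" if rng.random() < 0.5 else "right"
            other = "right" if bad_side == "left" else "left"
            kept_cand = _extend_terminal(
                GeneModel(f"g{g:03d}_h1", "homology", "Y", strand, exons), bad_side, 2
            )
            donor = _extend_terminal(
                GeneModel(f"g{g:03d}_h2", "homology", "Y", strand, exons), other, 5
            )
            homology.extend([kept_cand, donor])
        else:
            homology.append(GeneModel(f"g{g:03d}_h1", "homology", "Y", strand, exons))
            if rng.random() < 0.3 and len(exons) >= 2:
                homology.append(
                    _extend_terminal(
                        GeneModel(f"g{g:03d}_h3", "homology", "Y", strand, exons),
                        "right" if rng.random() < 0.5 else "left",
                        5,
                    )
                )
            if rng.random() < 0.2:
                # overlapping ab initio duplicate: must not be recruited
                abinitio.append(GeneModel(f"g{g:03d}_abdup", "abinitio", "Y", strand, exons))
        pos = exons[-1][1] + 3000 + int(rng.integers(5_000, 12_000))

    # intergenic ab initio decoys with one partially covered exon
    for d in range(max(1, config.n_genes // 10)):
        strand = "+" if rng.random() < 0.5 else "-"
        s = pos
        ln = int(rng.integers(200, 500))
        decoy = GeneModel(f"decoy{d:02d}", "abinitio", "Y", strand, ((s, s + ln),))
        abinitio.append(decoy)
        cover.append((s, s + int(0.9 * ln)))
        pos += ln + int(rng.integers(5_000, 12_000))

    return GeneEvidenceSet(
        homology=homology,
        abinitio=abinitio,
        transcript_cover=cover,
        junctions=junctions,
        truth_models=truth_models,
    )


# ---------------------------------------------------------------------------
# repeats


_FAMILIES = ["DNA/hAT", "LINE/L2", "LTR/Gypsy", "Helitron-4", "SINE/tRNA"]


def simulate_repeats(config: ScenarioConfig, truth: TruthSet) -> list[RepeatInterval]:
    """Repeat intervals with per-element transition/transversion proportions.

    Elements tile each region to the configured density; MSY elements are
    drawn from a younger (lower-divergence) distribution than PAR
    elements.  Per-element divergence d is split as P = 0.7 d (transitions)
    and Q = 0.3 d (transversions).
    """
    rng = config.rng("repeats")
    intervals: list[RepeatInterval] = []
    regions = [
        (truth.par_interval, config.repeat_density_par, config.repeat_age_par),
        (truth.msy_interval, config.repeat_density_msy, config.repeat_age_msy),
    ]
    mean_len = config.repeat_mean_len
    for (r0, r1), density, age in regions:
        if density <= 0 or r1 <= r0:
            continue
        mean_gap = mean_len * (1.0 - density) / density
        pos = r0
        while True:
            pos += int(rng.geometric(1.0 / max(mean_gap, 1.0)))
            if pos >= r1:
                break
            ln = max(50, int(rng.normal(mean_len, 0.3 * mean_len)))
            end = min(pos + ln, r1)
            if end - pos >= 30:
                d = float(np.clip(rng.normal(age, config.repeat_age_sd), 0.02, 0.45))
                intervals.append(
                    RepeatInterval(
                        chrom=truth.chrom,
                        start=pos,
                        end=end,
                        family=_FAMILIES[int(rng.integers(0, len(_FAMILIES)))],
                        P=0.7 * d,
                        Q=0.3 * d,
                    )
                )
            pos = end
    truth.repeat_intervals = intervals
    return intervals
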