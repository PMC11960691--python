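"""Evidence-based gene-model merging.

Gene models from homology alignment and ab initio prediction are combined
with transcriptome support (exon coverage intervals plus splice-junction
observations) into one consistent annotation:

1. overlapping homology models (same strand, >= 1 bp exonic overlap) are
   clustered;
2. within each cluster the model best supported by the transcriptome is
   kept;
3. if a kept model's terminal exon is poorly supported, the eliminated
   models of the cluster are screened for a junction-compatible,
   better-supported terminal exon, which then replaces it;
4. ab initio models overlapping no homology cluster are recruited when
   they are fully supported (every exonic base covered, every junction
   observed).

Spliced alignment and ORF finding are out of scope: transcript evidence is
consumed as coverage intervals and a junction list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .repeats import merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "SupportProfile",
    "MergedAnnotation",
    "compute_support",
    "cluster_models",
    "select_representative",
    "rescue_terminal_exons",
    "recruit_abinitio",
    "merge_annotation",
    "write_gff3",
    "read_gff3",
]

_FULL = 1.0 - 1e-9  # tolerance for "fully covered" on float fractions


@dataclass(frozen=True)
class GeneModel:
    model_id: str
    source: str  # "homology" | "abinitio"
    chrom: str
    strand: str  # "+" | "-"
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted, disjoint
    cds: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.model_id}: empty exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.model_id}: exons overlap or are unsorted")
            prev_end = e
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        if self.cds is None:
            return self.exonic_length
        lo, hi = self.cds
        return sum(max(0, min(e, hi) - max(s, lo)) for s, e in self.exons)


@dataclass
class SupportProfile:
    exon_cover: tuple[float, ...]  # covered-base fraction per exon
    junction_match: tuple[bool, ...]  # one flag per intron

    def __post_init__(self):
        if any(not 0 <= f <= 1 + 1e-12 for f in self.exon_cover):
            raise ValueError("exon coverage fractions must lie in [0, 1]")


@dataclass
class MergedAnnotation:
    kept: list[GeneModel]
    provenance: dict[str, str]  # model_id -> selected|terminal-rescued|recruited
    clusters: dict[str, int]  # model_id -> cluster index (homology models)
    recruited: list[GeneModel]

    @property
    def final_models(self) -> list[GeneModel]:
        return sorted(self.kept + self.recruited, key=lambda m: (m.chrom, m.start))


# ---------------------------------------------------------------------------
# support


def _covered(exon: tuple[int, int], cover: Sequence[tuple[int, int]]) -> int:
    s, e = exon
    return sum(max(0, min(ce, e) - max(cs, s)) for cs, ce in cover)


def compute_support(
    model: GeneModel,
    transcript_cover: Iterable[tuple[int, int]],
    junctions: Iterable[tuple[int, int, str]],
) -> tuple[SupportProfile, float]:
    """Per-exon coverage fractions, junction flags and a scalar score.

    ``transcript_cover`` lists genomic intervals covered by transcript
    evidence; ``junctions`` lists observed introns as (start, end, strand).
    The score averages the exon-coverage mean and the matched-junction
    fraction with equal weight; single-exon models use the exon term only.
    """
    cover = merge_intervals(transcript_cover)
    juncs = {(int(s), int(e), st) for s, e, st in junctions}
    fracs = tuple(_covered(x, cover) / (x[1] - x[0]) for x in model.exons)
    flags = tuple(
        (s, e, model.strand) in juncs for s, e in model.introns
    )
    profile = SupportProfile(exon_cover=fracs, junction_match=flags)
    exon_term = sum(fracs) / len(fracs)
    if flags:
        score = 0.5 * exon_term + 0.5 * (sum(flags) / len(flags))
    else:
        score = exon_term
    return profile, score


# ---------------------------------------------------------------------------
# clustering and selection


def _exonic_overlap(a: GeneModel, b: GeneModel) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.end <= b.start or b.end <= a.start:
        return False
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if min(e1, e2) > max(s1, s2):
                return True
    return False


def cluster_models(models: Sequence[GeneModel]) -> list[list[GeneModel]]:
    """Connected components under same-strand exonic overlap (>= 1 bp)."""
    n = len(models)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: (models[i].chrom, models[i].start))
    for ii in range(n):
        i = order[ii]
        for jj in range(ii + 1, n):
            j = order[jj]
            if models[j].chrom != models[i].chrom or models[j].start >= models[i].end:
                break
            if _exonic_overlap(models[i], models[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[GeneModel]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(models[i])
    clusters = [sorted(g, key=lambda m: (m.start, m.model_id)) for g in groups.values()]
    clusters.sort(key=lambda g: (g[0].chrom, g[0].start, g[0].model_id))
    return clusters


def select_representative(
    cluster: Sequence[GeneModel], scores: Mapping[str, float]
) -> tuple[GeneModel, list[GeneModel]]:
    """Keep the best-supported model; ties go to longer CDS, then smaller start."""
    ranked = sorted(
        cluster,
        key=lambda m: (-scores[m.model_id], -m.cds_length, m.start, m.model_id),
    )
    return ranked[0], ranked[1:]


# ---------------------------------------------------------------------------
# terminal-exon rescue


def _try_side(
    kept: GeneModel,
    eliminated: Sequence[GeneModel],
    profiles: Mapping[str, SupportProfile],
    side: str,
    tau: float,
) -> GeneModel | None:
    idx = 0 if side == "left" else -1
    kept_prof = profiles[kept.model_id]
    if kept_prof.exon_cover[idx] >= tau:
        return None
    kept_introns = list(kept.introns)
    required = set(kept_introns[1:] if side == "left" else kept_introns[:-1])

    best: tuple[float, str, GeneModel] | None = None
    for donor in eliminated:
        if donor.strand != kept.strand or donor.chrom != kept.chrom:
            continue
        if not set(donor.introns) >= required:
            continue  # incompatible internal junctions on the rescued side
        # the donor junction bounding the transplanted exon must splice
        # onto the kept model's neighbouring exon
        if len(kept.exons) > 1 and len(donor.exons) > 1:
            if side == "left" and donor.introns[0][1] != kept.exons[1][0]:
                continue
            if side == "right" and donor.introns[-1][0] != kept.exons[-2][1]:
                continue
        cov = profiles[donor.model_id].exon_cover[idx]
        if cov <= kept_prof.exon_cover[idx]:
            continue
        cand = (cov, donor.model_id, donor)
        if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    if best is None:
        return None
    donor = best[2]
    new_exon = donor.exons[idx]
    if side == "left":
        exons = (new_exon,) + kept.exons[1:]
        bad = len(kept.exons) > 1 and new_exon[1] >= kept.exons[1][0]
    else:
        exons = kept.exons[:-1] + (new_exon,)
        bad = len(kept.exons) > 1 and new_exon[0] <= kept.exons[-2][1]
    if bad:
        logger.warning(
            "terminal rescue of %s (%s end) from %s would create overlapping "
            "exons; rejected",
            kept.model_id,
            side,
            donor.model_id,
        )
        return None
    return replace(kept, exons=exons)


def rescue_terminal_exons(
    kept: GeneModel,
    eliminated: Sequence[GeneModel],
    profiles: Mapping[str, SupportProfile],
    tau: float = 0.5,
) -> tuple[GeneModel, bool]:
    """Replace poorly supported terminal exons from eliminated cluster members.

    A terminal exon with coverage fraction < ``tau`` is replaced by the
    best-covered terminal exon of an eliminated model that shares all of
    the kept model's internal junctions on the affected side and offers
    strictly greater coverage.  At most one replacement per end.  Returns
    the (possibly new) model and whether anything was replaced.
    """
    model = kept
    rescued = False
    for side in ("left", "right"):
        new = _try_side(model, eliminated, profiles, side, tau)
        if new is not None:
            model = new
            rescued = True
    return model, rescued


# ---------------------------------------------------------------------------
# ab initio recruitment


def _fully_supported(profile: SupportProfile) -> bool:
    return all(f >= _FULL for f in profile.exon_cover) and all(profile.junction_match)


def recruit_abinitio(
    abinitio_models: Sequence[GeneModel],
    homology_clusters: Sequence[Sequence[GeneModel]],
    profiles: Mapping[str, SupportProfile],
) -> list[GeneModel]:
    """Recruit ab initio models that are fully supported and overlap no cluster."""
    recruited = []
    flat = [m for cluster in homology_clusters for m in cluster]
    for model in sorted(abinitio_models, key=lambda m: (m.chrom, m.start, m.model_id)):
        if any(_exonic_overlap(model, h) for h in flat):
            continue
        if _fully_supported(profiles[model.model_id]):
            recruited.append(model)
    return recruited


# ---------------------------------------------------------------------------
# top-level merge


def merge_annotation(
    homology_models: Sequence[GeneModel],
    abinitio_models: Sequence[GeneModel],
    transcript_cover: Iterable[tuple[int, int]],
    junctions: Iterable[tuple[int, int, str]],
    tau: float = 0.5,
) -> MergedAnnotation:
    cover = merge_intervals(transcript_cover)
    juncs = list(junctions)

    profiles: dict[str, SupportProfile] = {}
    scores: dict[str, float] = {}
    for m in list(homology_models) + list(abinitio_models):
        profiles[m.model_id], scores[m.model_id] = compute_support(m, cover, juncs)

    clusters = cluster_models(homology_models)
    cluster_of = {
        m.model_id: i for i, cluster in enumerate(clusters) for m in cluster
    }

    kept: list[GeneModel] = []
    provenance: dict[str, str] = {}
    for cluster in clusters:
        rep, eliminated = select_representative(cluster, scores)
        model, rescued = rescue_terminal_exons(rep, eliminated, profiles, tau=tau)
        if rescued:
            # support of the rescued structure is re-evaluated for output
            profiles[model.model_id], scores[model.model_id] = compute_support(
                model, cover, juncs
            )
        kept.append(model)
        provenance[model.model_id] = "terminal-rescued" if rescued else "selected"

    recruited = recruit_abinitio(abinitio_models, clusters, profiles)
    for m in recruited:
        provenance[m.model_id] = "recruited"

    return MergedAnnotation(
        kept=kept, provenance=provenance, clusters=cluster_of, recruited=recruited
    )


# ---------------------------------------------------------------------------
# GFF3 I/O (gene -> mRNA -> exon; 1-based inclusive on disk)


def write_gff3(models: Sequence[GeneModel], path, provenance: Mapping[str, str] | None = None) -> None:
    provenance = provenance or {}
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.model_id)):
            note = provenance.get(m.model_id, "")
            attrs = f"ID={m.model_id};source_class={m.source}"
            if note:
                attrs += f";note={note}"
            fh.write(
                f"{m.chrom}\tmsypipe\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.chrom}\tmsypipe\tmRNA\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.model_id}.t1;Parent={m.model_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tmsypipe\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.model_id}.e{i};Parent={m.model_id}.t1\n"
                )


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from a gene -> mRNA -> exon GFF3 hierarchy."""
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attr_text = f[:9]
            attrs = _parse_attrs(attr_text)
            if ftype == "gene":
                genes[attrs["ID"]] = {
                    "chrom": chrom,
                    "strand": strand,
                    "source": attrs.get("source_class", "homology"),
                    "exons": [],
                }
            elif ftype == "mRNA":
                mrna_to_gene[attrs["ID"]] = attrs["Parent"]
            elif ftype == "exon":
                gene_id = mrna_to_gene.get(attrs.get("Parent", ""), attrs.get("Parent"))
                if gene_id in genes:
                    genes[gene_id]["exons"].append((int(start) - 1, int(end)))
    models = []
    for gid, g in genes.items():
        models.append(
            GeneModel(
                model_id=gid,
                source=g["source"],
                chrom=g["chrom"],
                strand=g["strand"],
                exons=tuple(sorted(g["exons"])),
            )
        )
    return sorted(models, key=lambda m: (m.chrom, m.start, m.model_id))
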