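"""RAD-tag sex-marker analysis.

Per-individual tag reads are collapsed and merged into a catalog by
single-linkage clustering at a small Hamming distance (equal-length tags
only), the presence tile table by number of females/males is computed, tags
present only in males are called, mapped back to the Y assembly by ungapped
seed-and-extend with a Karlin-Altschul E-value cutoff, and their positional
enrichment in a region (e.g. the distal 16% of the chromosome) is tested
with an exact binomial test.

Restriction-site library simulation and demultiplexing are out of scope;
inputs are reads or tag-count tables per individual.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import _kmer_codes, revcomp

__all__ = [
    "TagCatalog",
    "TileTable",
    "TagHit",
    "build_tag_catalog",
    "tile_distribution",
    "call_male_only_tags",
    "map_tags",
    "region_enrichment",
]

# ungapped nucleotide Karlin-Altschul parameters for match +1 / mismatch -2
KA_LAMBDA = 1.28
KA_K = 0.46
MATCH_SCORE = 1
MISMATCH_SCORE = -2


@dataclass
class TagCatalog:
    tags: pd.DataFrame  # tag_id, sequence
    depth: pd.DataFrame  # tags x individuals, non-negative ints
    sex: pd.Series  # individual -> "M" | "F"

    @property
    def males(self) -> list[str]:
        return [i for i in self.depth.columns if self.sex[i] == "M"]

    @property
    def females(self) -> list[str]:
        return [i for i in self.depth.columns if self.sex[i] == "F"]

    def sequence_of(self, tag_id: str) -> str:
        row = self.tags.loc[self.tags["tag_id"] == tag_id, "sequence"]
        return str(row.iloc[0])


@dataclass
class TileTable:
    counts: np.ndarray  # counts[f][m] = tags present in f females and m males

    def to_frame(self) -> pd.DataFrame:
        nf, nm = self.counts.shape
        return pd.DataFrame(
            self.counts,
            index=pd.Index(range(nf), name="n_females"),
            columns=pd.Index(range(nm), name="n_males"),
        )


@dataclass(frozen=True)
class TagHit:
    tag_id: str
    t_position: int  # best-hit left coordinate, 0-based
    score: int
    evalue: float
    strand: str = "+"


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _as_counter(reads) -> Counter:
    if isinstance(reads, Mapping):
        return Counter({str(s).upper(): int(c) for s, c in reads.items()})
    return Counter(str(s).upper() for s in reads)


def build_tag_catalog(
    per_individual_reads: Mapping[str, Iterable[str] | Mapping[str, int]],
    sex_labels: Mapping[str, str],
    max_mismatch: int = 2,
    block: int = 128,
) -> TagCatalog:
    """Collapse reads per individual and merge across individuals.

    Identical reads collapse to per-individual counts; catalog tags are the
    connected components of single-linkage clustering at <= ``max_mismatch``
    substitutions between equal-length sequences.  Reads of unequal length
    are never merged.  The component representative is its most abundant
    sequence (ties to the lexicographically smaller one).
    """
    individuals = list(per_individual_reads)
    counters = {ind: _as_counter(per_individual_reads[ind]) for ind in individuals}
    total: Counter = Counter()
    for c in counters.values():
        total.update(c)
    seqs = sorted(total)

    uf = _UnionFind(len(seqs))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for length, idx in by_len.items():
        if len(idx) < 2:
            continue
        arr = np.frombuffer("".join(seqs[i] for i in idx).encode(), dtype=np.uint8)
        arr = arr.reshape(len(idx), length)
        for lo in range(0, len(idx), block):
            hi = min(lo + block, len(idx))
            mism = (arr[lo:hi, None, :] != arr[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(mism <= max_mismatch)
            for a, b in zip(ii, jj):
                ga = idx[lo + a]
                gb = idx[b]
                if ga != gb:
                    uf.union(ga, gb)

    components: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        components.setdefault(uf.find(i), []).append(i)
    reps = []
    for members in components.values():
        rep = min(members, key=lambda i: (-total[seqs[i]], seqs[i]))
        reps.append((seqs[rep], [seqs[i] for i in members]))
    reps.sort(key=lambda r: r[0])

    tag_ids = [f"tag{i:06d}" for i in range(len(reps))]
    depth = np.zeros((len(reps), len(individuals)), dtype=np.int64)
    for r, (_, members) in enumerate(reps):
        for c, ind in enumerate(individuals):
            cnt = counters[ind]
            depth[r, c] = sum(cnt.get(m, 0) for m in members)
    tags = pd.DataFrame({"tag_id": tag_ids, "sequence": [r[0] for r in reps]})
    return TagCatalog(
        tags=tags,
        depth=pd.DataFrame(depth, index=tag_ids, columns=individuals),
        sex=pd.Series({ind: sex_labels[ind] for ind in individuals}),
    )


def tile_distribution(catalog: TagCatalog, min_depth: int = 1) -> TileTable:
    """Contingency cube: tags by number of females/males with presence.

    Presence means depth >= ``min_depth``.  Cell sums equal the number of
    catalog tags.
    """
    present = catalog.depth.to_numpy() >= min_depth
    is_male = np.array([catalog.sex[i] == "M" for i in catalog.depth.columns])
    m = present[:, is_male].sum(axis=1)
    f = present[:, ~is_male].sum(axis=1)
    counts = np.zeros((int((~is_male).sum()) + 1, int(is_male.sum()) + 1), dtype=np.int64)
    np.add.at(counts, (f, m), 1)
    return TileTable(counts=counts)


def call_male_only_tags(
    catalog: TagCatalog,
    min_males: int,
    max_females: int = 0,
    min_depth: int = 1,
) -> list[str]:
    """Tags present in >= min_males males and <= max_females females."""
    present = catalog.depth.to_numpy() >= min_depth
    is_male = np.array([catalog.sex[i] == "M" for i in catalog.depth.columns])
    m = present[:, is_male].sum(axis=1)
    f = present[:, ~is_male].sum(axis=1)
    mask = (m >= min_males) & (f <= max_females)
    return [tid for tid, keep in zip(catalog.depth.index, mask) if keep]


# ---------------------------------------------------------------------------
# mapping


class _SeedIndex:
    """Sorted k-mer code index over the target sequence."""

    def __init__(self, target: str, k: int):
        self.k = k
        codes, valid = _kmer_codes(target, k)
        pos = np.flatnonzero(valid)
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def lookup(self, code: int) -> np.ndarray:
        code = np.uint64(code)
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.pos[lo:hi]

    def lookup_many(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        codes = codes.astype(np.uint64, copy=False)
        return (
            np.searchsorted(self.codes, codes, side="left"),
            np.searchsorted(self.codes, codes, side="right"),
        )


def _best_segment(scores: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring contiguous segment (Kadane): (score, start, end)."""
    best = cur = 0
    best_s = best_e = cur_s = 0
    for i, v in enumerate(scores):
        if cur <= 0:
            cur = int(v)
            cur_s = i
        else:
            cur += int(v)
        if cur > best:
            best, best_s, best_e = cur, cur_s, i + 1
    return best, best_s, best_e


def evalue(score: float, m: int, n: int, lam: float = KA_LAMBDA, K: float = KA_K) -> float:
    """Ungapped Karlin-Altschul E-value, E = K m n exp(-lambda S)."""
    log_e = math.log(K) + math.log(m) + math.log(n) - lam * score
    return math.exp(log_e) if log_e > -700 else 0.0


def map_tags(
    tags: Iterable[tuple[str, str]],
    y_sequence: str,
    evalue_max: float = 1e-40,
    k: int = 15,
    match: int = MATCH_SCORE,
    mismatch: int = MISMATCH_SCORE,
    lam: float = KA_LAMBDA,
    ka_k: float = KA_K,
    index: "_SeedIndex | None" = None,
    max_diagonals: int = 64,
) -> list[TagHit]:
    """Ungapped seed-and-extend best hit per tag with an E-value cutoff.

    Every tag k-mer seeds candidate diagonals; along each diagonal the
    maximal-scoring ungapped segment is taken (match +1 / mismatch -2) and
    E = K m n exp(-lambda S) with the ungapped nucleotide constants.  The
    best hit per tag keeps the highest score, ties broken to the smallest
    target coordinate (plus strand preferred); hits with E > ``evalue_max``
    are discarded.
    """
    if index is None:
        index = _SeedIndex(y_sequence, k)
    n = len(y_sequence)
    y_arr = np.frombuffer(y_sequence.encode(), dtype=np.uint8)
    hits: list[TagHit] = []
    for tag_id, seq in tags:
        best: tuple[int, int, str] | None = None  # (score, t_pos, strand)
        m = len(seq)
        for strand in ("+", "-"):
            s = seq.upper() if strand == "+" else revcomp(seq.upper())
            codes, valid = _kmer_codes(s, index.k)
            qis = np.flatnonzero(valid)
            lo, hi = index.lookup_many(codes[qis])
            diagonals: list[int] = []
            seen: set[int] = set()
            for qi, l, h in zip(qis, lo, hi):
                for tp in index.pos[l:h]:
                    d = int(tp) - int(qi)
                    if d not in seen:
                        seen.add(d)
                        diagonals.append(d)
                if len(seen) >= max_diagonals:
                    break
            tag_arr = np.frombuffer(s.encode(), dtype=np.uint8)
            for d in diagonals:
                q0 = max(0, -d)
                q1 = min(m, n - d)
                if q1 <= q0:
                    continue
                eq = tag_arr[q0:q1] == y_arr[d + q0 : d + q1]
                scores = np.where(eq, match, mismatch)
                sc, s0, _ = _best_segment(scores)
                t_pos = d + q0 + s0
                cand = (sc, t_pos, strand)
                if best is None or sc > best[0] or (
                    sc == best[0]
                    and (t_pos, strand) < (best[1], best[2])
                ):
                    best = cand
        if best is None:
            continue
        e = evalue(best[0], m, n, lam=lam, K=ka_k)
        if e <= evalue_max:
            hits.append(TagHit(tag_id, best[1], best[0], e, best[2]))
    return hits


def region_enrichment(
    hits: Sequence[TagHit], region_interval: tuple[int, int], chrom_length: int
) -> tuple[float, float]:
    """Fraction of best hits inside a region and a one-sided binomial p.

    The null expectation p0 is the region's share of the chromosome; the
    test is exact, P[Bin(n, p0) >= k].
    """
    r0, r1 = region_interval
    if not hits:
        return 0.0, 1.0
    inside = sum(1 for h in hits if r0 <= h.t_position < r1)
    p0 = (r1 - r0) / chrom_length
    res = stats.binomtest(inside, len(hits), p0, alternative="greater")
    return inside / len(hits), float(res.pvalue)
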