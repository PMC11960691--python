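"""Orthologous X-Y alignment and the windowed SNP+indel divergence statistic.

The alignment route mirrors the classical chain/net post-processing of
local genome alignments at desk scale: exact unique k-mer seeds are
collected (``seed_anchors``), chained co-linearly with affine gap costs
(``chain_anchors``), inter-anchor gaps are realigned base-by-base with a
global affine aligner (``fill_chain_gaps``), and chains are netted into a
single-coverage tiling of the target (``net_chains``).  The Y chromosome is
the alignment *target*, the X the *query*; windows are indexed on Y.

Per 10 kb window the statistic is

    divergence_pct = 100 * (mismatch columns + gap columns) / aligned columns

i.e. indels are counted as gap *columns* (bases), which bounds the
proportion by 1; an event-count mode is available.  The PAR/MSY boundary is
the single changepoint minimizing the within-segment squared error of the
window series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align

__all__ = [
    "Anchor",
    "ChainSkeleton",
    "AlignmentChain",
    "WindowDivergence",
    "BoundaryCall",
    "seed_anchors",
    "chain_anchors",
    "fill_chain_gaps",
    "net_chains",
    "window_divergence",
    "detect_boundary",
    "align_chromosomes",
    "divergence_profile",
    "write_paf",
    "read_paf",
]

# per-column classes
MATCH, MISMATCH, T_GAP, Q_GAP = 0, 1, 2, 3
# T_GAP: gap in the target (column consumes query only)
# Q_GAP: gap in the query  (column consumes target only)

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_OPEN = 2.0  # affine gap of length g costs open + g * extend
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class Anchor:
    q_start: int
    t_start: int
    length: int
    strand: str = "+"

    @property
    def q_end(self) -> int:
        return self.q_start + self.length

    @property
    def t_end(self) -> int:
        return self.t_start + self.length


@dataclass
class ChainSkeleton:
    anchors: list[Anchor]
    score: float
    strand: str = "+"


@dataclass
class Block:
    t_start: int
    q_start: int
    cols: np.ndarray  # uint8 column classes

    @property
    def consumes_t(self) -> np.ndarray:
        return self.cols != T_GAP

    @property
    def consumes_q(self) -> np.ndarray:
        return self.cols != Q_GAP

    @property
    def t_end(self) -> int:
        return self.t_start + int(self.consumes_t.sum())

    @property
    def q_end(self) -> int:
        return self.q_start + int(self.consumes_q.sum())

    def t_positions(self) -> np.ndarray:
        """Target coordinate of each column's left flank."""
        c = self.consumes_t.astype(np.int64)
        return np.maximum(self.t_start + np.cumsum(c) - 1, self.t_start)


@dataclass
class AlignmentChain:
    blocks: list[Block]
    score: float
    strand: str = "+"
    flagged_gaps: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def t_start(self) -> int:
        return self.blocks[0].t_start

    @property
    def t_end(self) -> int:
        return self.blocks[-1].t_end

    def column_counts(self) -> dict[str, int]:
        counts = {"match": 0, "mismatch": 0, "t_gap": 0, "q_gap": 0}
        for b in self.blocks:
            bc = np.bincount(b.cols, minlength=4)
            counts["match"] += int(bc[MATCH])
            counts["mismatch"] += int(bc[MISMATCH])
            counts["t_gap"] += int(bc[T_GAP])
            counts["q_gap"] += int(bc[Q_GAP])
        return counts


# ---------------------------------------------------------------------------
# seeding


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers and a validity mask (no ambiguous base)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = arr[j : j + n]
        codes = codes * np.uint64(4) + window.astype(np.uint64)
        valid &= window < 4
    return codes, valid


def _unique_kmer_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of k-mers occurring exactly once in the sequence."""
    codes, valid = _kmer_codes(seq, k)
    pos = np.flatnonzero(valid)
    codes = codes[pos]
    order = np.argsort(codes, kind="stable")
    sc, sp = codes[order], pos[order]
    if len(sc) == 0:
        return sc, sp
    boundary = np.empty(len(sc) + 1, dtype=bool)
    boundary[0] = boundary[-1] = True
    boundary[1:-1] = sc[1:] != sc[:-1]
    starts = np.flatnonzero(boundary[:-1])
    ends = np.flatnonzero(boundary[1:]) + 1
    single = (ends - starts) == 1
    idx = starts[single]
    return sc[idx], sp[idx]


def _merge_comatches(ts: np.ndarray, qs: np.ndarray, k: int, strand: str) -> list[Anchor]:
    if len(ts) == 0:
        return []
    diag = ts - qs
    order = np.lexsort((ts, diag))
    ts, qs, diag = ts[order], qs[order], diag[order]
    brk = np.flatnonzero((np.diff(diag) != 0) | (np.diff(ts) != 1))
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk + 1, [len(ts)]])
    return [
        Anchor(
            q_start=int(qs[s]),
            t_start=int(ts[s]),
            length=int(ts[e - 1] - ts[s]) + k,
            strand=strand,
        )
        for s, e in zip(starts, ends)
    ]


def seed_anchors(x_sequence: str, y_sequence: str, k: int = 15) -> list[Anchor]:
    """All maximal unique exact k-mer co-matches between X (query) and Y (target).

    A co-match requires the k-mer to occur exactly once in each sequence;
    runs of co-matches on the same diagonal are merged into maximal
    anchors.  Reverse-complement matches of the query are reported with
    strand "-" (coordinates on the reverse-complemented query frame are
    mapped back to forward X coordinates).
    """
    if k < 11:
        raise ValueError("seed k must be >= 11")
    if not x_sequence or not y_sequence:
        raise ValueError("sequences must be non-empty")
    yc, yp = _unique_kmer_positions(y_sequence, k)
    anchors: list[Anchor] = []

    xc, xp = _unique_kmer_positions(x_sequence, k)
    _, yi, xi = np.intersect1d(yc, xc, assume_unique=True, return_indices=True)
    anchors += _merge_comatches(yp[yi], xp[xi], k, "+")
    matched_fwd = set(map(int, yp[yi]))

    xr = revcomp(x_sequence)
    xc_r, xp_r = _unique_kmer_positions(xr, k)
    _, yi_r, xi_r = np.intersect1d(yc, xc_r, assume_unique=True, return_indices=True)
    if len(yi_r):
        keep = np.array([int(t) not in matched_fwd for t in yp[yi_r]], dtype=bool)
        minus = _merge_comatches(yp[yi_r][keep], xp_r[xi_r][keep], k, "-")
        n = len(x_sequence)
        anchors += [
            Anchor(
                q_start=n - a.q_start - a.length,
                t_start=a.t_start,
                length=a.length,
                strand="-",
            )
            for a in minus
        ]
    anchors.sort(key=lambda a: (a.t_start, a.q_start))
    return anchors


# ---------------------------------------------------------------------------
# chaining


def _gap_cost(dt: int, dq: int, gap_open: float, gap_extend: float) -> float:
    g = abs(dt - dq)
    return 0.0 if g == 0 else gap_open + gap_extend * g


def _eff_q(anchor: Anchor) -> tuple[int, int]:
    """(start, end) on an axis that increases with t regardless of strand."""
    if anchor.strand == "+":
        return anchor.q_start, anchor.q_end
    return -(anchor.q_start + anchor.length), -anchor.q_start


def chain_anchors(
    anchors: Sequence[Anchor],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    lookback: int = 64,
    max_chains: int = 10_000,
) -> list[ChainSkeleton]:
    """Co-linear chaining maximizing anchored bases minus affine gap cost.

    Dynamic programming over anchors sorted by target start, with a bounded
    predecessor window (exact whenever the window covers all predecessors,
    e.g. for small inputs).  Chains are extracted greedily by score until
    every anchor is used; anchors within a chain are strictly increasing on
    both coordinates.
    """
    chains: list[ChainSkeleton] = []
    for strand in ("+", "-"):
        pool = sorted(
            (a for a in anchors if a.strand == strand),
            key=lambda a: (a.t_start, _eff_q(a)[0]),
        )
        while pool and len(chains) < max_chains:
            n = len(pool)
            t_start = np.array([a.t_start for a in pool])
            t_end = np.array([a.t_end for a in pool])
            eff = [_eff_q(a) for a in pool]
            dp = np.array([float(a.length) for a in pool])
            parent = np.full(n, -1, dtype=int)
            for i in range(n):
                best = 0.0
                best_j = -1
                ei0 = eff[i][0]
                ti0 = t_start[i]
                for j in range(max(0, i - lookback), i):
                    dt = ti0 - t_end[j]
                    dq = ei0 - eff[j][1]
                    if dt < 0 or dq < 0:
                        continue
                    cand = dp[j] - _gap_cost(dt, dq, gap_open, gap_extend)
                    if cand > best:
                        best, best_j = cand, j
                dp[i] += best
                parent[i] = best_j
            # accept every chain whose traceback is conflict-free this round;
            # conflicting (shared-anchor) chains are re-solved next round
            order = sorted(range(n), key=lambda i: (-dp[i], t_start[i]))
            taken = np.zeros(n, dtype=bool)
            for end in order:
                if taken[end]:
                    continue
                idx = []
                i = end
                ok = True
                while i != -1:
                    if taken[i]:
                        ok = False
                        break
                    idx.append(i)
                    i = parent[i]
                if not ok:
                    continue
                idx.reverse()
                taken[idx] = True
                chains.append(
                    ChainSkeleton(
                        anchors=[pool[i] for i in idx],
                        score=float(dp[end]),
                        strand=strand,
                    )
                )
                if len(chains) >= max_chains:
                    break
            pool = [a for i, a in enumerate(pool) if not taken[i]]
            if not taken.any():
                break
    chains.sort(key=lambda c: (-c.score, c.anchors[0].t_start))
    return chains


# ---------------------------------------------------------------------------
# gap filling


def _make_aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython scores the first gap position with open_gap_score, so a
    # length-g gap costs open + g * extend under our convention
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _compare_cols(ys: str, xs: str) -> np.ndarray:
    a = np.frombuffer(ys.encode(), dtype=np.uint8)
    b = np.frombuffer(xs.encode(), dtype=np.uint8)
    return np.where(a == b, MATCH, MISMATCH).astype(np.uint8)


def _align_gap(xs: str, ys: str, aligner) -> np.ndarray:
    """Column classes of a global alignment of a query gap vs target gap."""
    if not xs and not ys:
        return np.empty(0, dtype=np.uint8)
    if not xs:
        return np.full(len(ys), Q_GAP, dtype=np.uint8)
    if not ys:
        return np.full(len(xs), T_GAP, dtype=np.uint8)
    aln = aligner.align(ys, xs)[0]
    t_blocks, q_blocks = aln.aligned
    parts: list[np.ndarray] = []
    pt = pq = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts > pt:
            parts.append(np.full(ts - pt, Q_GAP, dtype=np.uint8))
        if qs > pq:
            parts.append(np.full(qs - pq, T_GAP, dtype=np.uint8))
        parts.append(_compare_cols(ys[ts:te], xs[qs:qe]))
        pt, pq = te, qe
    if len(ys) > pt:
        parts.append(np.full(len(ys) - pt, Q_GAP, dtype=np.uint8))
    if len(xs) > pq:
        parts.append(np.full(len(xs) - pq, T_GAP, dtype=np.uint8))
    return np.concatenate(parts)


def _score_cols(cols: np.ndarray, match, mismatch, gap_open, gap_extend) -> float:
    if len(cols) == 0:
        return 0.0
    bc = np.bincount(cols, minlength=4)
    is_gap = (cols == T_GAP) | (cols == Q_GAP)
    # number of gap runs (affine opens)
    opens = int(is_gap[0]) + int(np.sum(is_gap[1:] & ~is_gap[:-1]))
    return (
        match * bc[MATCH]
        + mismatch * bc[MISMATCH]
        - gap_open * opens
        - gap_extend * (bc[T_GAP] + bc[Q_GAP])
    )


def fill_chain_gaps(
    skeleton: ChainSkeleton,
    x_sequence: str,
    y_sequence: str,
    max_gap: int = 20_000,
    extend_to: tuple[int, int, int, int] | None = None,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    max_fill_area: int = 1_000_000,
) -> AlignmentChain:
    """Base-level chain: global affine realignment of all inter-anchor gaps.

    Gaps longer than ``max_gap`` on either side, or whose DP matrix would
    exceed ``max_fill_area`` cells, are left unaligned and flagged,
    splitting the chain into separate blocks (such alignment deserts only
    occur between weakly chained anchors, never inside a well-anchored
    orthologous chain).  ``extend_to`` = (t_lo, t_hi, q_lo, q_hi)
    additionally aligns the regions between the chain termini and those
    bounds (used for the outermost chain so that sequence ends are
    covered).  For strand "-", query coordinates refer to the
    reverse-complemented X.
    """
    query = x_sequence if skeleton.strand == "+" else revcomp(x_sequence)
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    anchors = sorted(skeleton.anchors, key=lambda a: a.t_start)
    if skeleton.strand == "-":
        n = len(x_sequence)
        anchors = [
            Anchor(n - a.q_start - a.length, a.t_start, a.length, "-") for a in anchors
        ]

    blocks: list[Block] = []
    flagged: list[tuple[int, int, int, int]] = []
    cur_cols: list[np.ndarray] = []
    cur_t = cur_q = None

    def _too_big(xs: str, ys: str) -> bool:
        return max(len(xs), len(ys)) > max_gap or len(xs) * len(ys) > max_fill_area

    def _flush():
        nonlocal cur_cols, cur_t, cur_q
        if cur_cols:
            blocks.append(Block(cur_t, cur_q, np.concatenate(cur_cols)))
        cur_cols, cur_t, cur_q = [], None, None

    prev_t = prev_q = None
    if extend_to is not None:
        t_lo, t_hi, q_lo, q_hi = extend_to
        first = anchors[0]
        xs, ys = query[q_lo : first.q_start], y_sequence[t_lo : first.t_start]
        if xs or ys:
            if not _too_big(xs, ys):
                cur_t, cur_q = t_lo, q_lo
                cur_cols.append(_align_gap(xs, ys, aligner))
            else:
                flagged.append((t_lo, first.t_start, q_lo, first.q_start))

    for a in anchors:
        if prev_t is not None:
            xs = query[prev_q : a.q_start]
            ys = y_sequence[prev_t : a.t_start]
            if _too_big(xs, ys):
                flagged.append((prev_t, a.t_start, prev_q, a.q_start))
                _flush()
            elif xs or ys:
                cur_cols.append(_align_gap(xs, ys, aligner))
        if cur_t is None:
            cur_t, cur_q = a.t_start, a.q_start
        cur_cols.append(np.full(a.length, MATCH, dtype=np.uint8))
        prev_t, prev_q = a.t_end, a.q_end

    if extend_to is not None:
        t_lo, t_hi, q_lo, q_hi = extend_to
        xs, ys = query[prev_q:q_hi], y_sequence[prev_t:t_hi]
        if xs or ys:
            if not _too_big(xs, ys):
                cur_cols.append(_align_gap(xs, ys, aligner))
            else:
                flagged.append((prev_t, t_hi, prev_q, q_hi))
    _flush()

    score = sum(
        _score_cols(b.cols, match, mismatch, gap_open, gap_extend) for b in blocks
    )
    return AlignmentChain(
        blocks=blocks, score=float(score), strand=skeleton.strand, flagged_gaps=flagged
    )


# ---------------------------------------------------------------------------
# netting


def _subtract_spans(
    runs_pos: np.ndarray, forbidden: list[tuple[int, int]]
) -> np.ndarray:
    """Boolean keep-mask over positions not inside any forbidden span."""
    keep = np.ones(len(runs_pos), dtype=bool)
    for s, e in forbidden:
        keep &= ~((runs_pos >= s) & (runs_pos < e))
    return keep


def net_chains(chains: Sequence[AlignmentChain]) -> list[AlignmentChain]:
    """Single-coverage netting: greedy by score, overlaps trimmed on target.

    Chains are accepted in order of descending score; columns whose target
    coordinate falls inside an already-kept span are removed, the remainder
    split into blocks.  The result is a non-overlapping tiling of the
    target by the highest-scoring (orthologous) chains.
    """
    kept_spans: list[tuple[int, int]] = []
    out: list[AlignmentChain] = []
    for chain in sorted(chains, key=lambda c: (-c.score, c.blocks[0].t_start if c.blocks else 0)):
        new_blocks: list[Block] = []
        for block in chain.blocks:
            if len(block.cols) == 0:
                continue
            tpos = block.t_positions()
            keep = _subtract_spans(tpos, kept_spans)
            if not keep.any():
                continue
            cons_t = block.consumes_t.astype(np.int64)
            cons_q = block.consumes_q.astype(np.int64)
            t_off = block.t_start + np.concatenate([[0], np.cumsum(cons_t)[:-1]])
            q_off = block.q_start + np.concatenate([[0], np.cumsum(cons_q)[:-1]])
            brk = np.flatnonzero(np.diff(keep.astype(np.int8)) != 0) + 1
            bounds = np.concatenate([[0], brk, [len(keep)]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                if not keep[s]:
                    continue
                new_blocks.append(
                    Block(int(t_off[s]), int(q_off[s]), block.cols[s:e].copy())
                )
        if not new_blocks:
            continue
        trimmed = AlignmentChain(
            blocks=new_blocks,
            score=chain.score,
            strand=chain.strand,
            flagged_gaps=chain.flagged_gaps,
        )
        for b in new_blocks:
            if b.t_end > b.t_start:
                kept_spans.append((b.t_start, b.t_end))
        out.append(trimmed)
    out.sort(key=lambda c: c.blocks[0].t_start)
    return out


# ---------------------------------------------------------------------------
# windows


@dataclass
class WindowDivergence:
    t_chrom: str
    t_start: int
    t_end: int
    aligned_cols: int
    n_snp: int
    n_indel_cols: int
    divergence_pct: float
    covered_fraction: float
    low_confidence: bool


def window_divergence(
    netted_chains: Sequence[AlignmentChain],
    window_bp: int = 10_000,
    step_bp: int | None = None,
    chrom: str = "Y",
    chrom_length: int | None = None,
    min_cov: float = 0.25,
    indel_events: bool = False,
) -> list[WindowDivergence]:
    """Windowed SNP+indel divergence along the target (Y) coordinate.

    Columns are assigned to windows by the target coordinate of their left
    flank.  ``divergence_pct`` is 100 * (mismatch + gap columns) / aligned
    columns; with ``indel_events=True`` each gap run counts once instead of
    per column.  Windows with a covered fraction below ``min_cov`` are
    flagged low-confidence.
    """
    step = step_bp or window_bp
    pos_list, cls_list = [], []
    for chain in netted_chains:
        for b in chain.blocks:
            if len(b.cols):
                pos_list.append(b.t_positions())
                cls_list.append(b.cols)
    if pos_list:
        pos = np.concatenate(pos_list)
        cls = np.concatenate(cls_list)
        order = np.argsort(pos, kind="stable")
        pos, cls = pos[order], cls[order]
    else:
        pos = np.empty(0, dtype=np.int64)
        cls = np.empty(0, dtype=np.uint8)

    if chrom_length is None:
        chrom_length = int(pos.max()) + 1 if len(pos) else window_bp

    is_gap = (cls == T_GAP) | (cls == Q_GAP)
    if indel_events:
        # count each gap run once, at its first column
        run_start = is_gap & ~np.concatenate([[False], is_gap[:-1]])
        gap_pos = pos[run_start]
    else:
        gap_pos = pos[is_gap]
    mm_pos = pos[cls == MISMATCH]
    cons_pos = pos[cls != T_GAP]  # target-consuming columns, own coordinate

    starts = np.arange(0, max(chrom_length - 1, 0) + 1, step, dtype=np.int64)
    starts = starts[starts < chrom_length]
    ends = np.minimum(starts + window_bp, chrom_length)

    def _count(sorted_pos):
        return np.searchsorted(sorted_pos, ends, side="left") - np.searchsorted(
            sorted_pos, starts, side="left"
        )

    n_all = _count(pos)
    n_gap = _count(gap_pos)
    n_mm = _count(mm_pos)
    n_cons = _count(cons_pos)

    windows = []
    for i in range(len(starts)):
        aligned = int(n_all[i])
        width = int(ends[i] - starts[i])
        covered = float(n_cons[i]) / width if width else 0.0
        div = 100.0 * (int(n_mm[i]) + int(n_gap[i])) / max(aligned, 1)
        windows.append(
            WindowDivergence(
                t_chrom=chrom,
                t_start=int(starts[i]),
                t_end=int(ends[i]),
                aligned_cols=aligned,
                n_snp=int(n_mm[i]),
                n_indel_cols=int(n_gap[i]),
                divergence_pct=div,
                covered_fraction=covered,
                low_confidence=covered < min_cov,
            )
        )
    return windows


def windows_frame(windows: Sequence[WindowDivergence]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [w.t_chrom for w in windows],
            "start": [w.t_start for w in windows],
            "end": [w.t_end for w in windows],
            "aligned_cols": [w.aligned_cols for w in windows],
            "n_snp": [w.n_snp for w in windows],
            "n_indel_cols": [w.n_indel_cols for w in windows],
            "divergence_pct": [w.divergence_pct for w in windows],
            "covered_fraction": [w.covered_fraction for w in windows],
            "low_confidence": [w.low_confidence for w in windows],
        }
    )


# ---------------------------------------------------------------------------
# boundary detection


@dataclass
class BoundaryCall:
    changepoint_bp: int
    mean_before: float
    mean_after: float
    fold: float
    msy_interval: tuple[int, int]
    no_transition: bool
    n_windows_used: int


def detect_boundary(
    windows: Sequence[WindowDivergence],
    min_windows_per_side: int = 5,
    fold_threshold: float = 1.5,
    include_low_confidence: bool = False,
) -> BoundaryCall:
    """Single changepoint of the divergence series by exhaustive SSE scan.

    The changepoint is the window edge minimizing total within-segment
    squared error; ties are broken to the rightmost edge.  When the
    after/before fold is below ``fold_threshold`` the call is flagged
    "no transition".  Low-confidence windows are excluded by default.
    """
    used = [w for w in windows if include_low_confidence or not w.low_confidence]
    used.sort(key=lambda w: w.t_start)
    n = len(used)
    if n < 2 * min_windows_per_side:
        raise ValueError(
            f"need at least {2 * min_windows_per_side} usable windows, got {n}"
        )
    d = np.array([w.divergence_pct for w in used])
    c1 = np.concatenate([[0.0], np.cumsum(d)])
    c2 = np.concatenate([[0.0], np.cumsum(d * d)])
    total = c1[n]
    total2 = c2[n]
    js = np.arange(min_windows_per_side, n - min_windows_per_side + 1)
    left_n = js.astype(float)
    left_s = c1[js]
    left_s2 = c2[js]
    right_n = n - left_n
    right_s = total - left_s
    right_s2 = total2 - left_s2
    sse = (left_s2 - left_s**2 / left_n) + (right_s2 - right_s**2 / right_n)
    best = js[np.flatnonzero(sse <= sse.min() + 1e-12)[-1]]
    mean_before = float(d[:best].mean())
    mean_after = float(d[best:].mean())
    if mean_before > 0:
        fold = mean_after / mean_before
    else:
        fold = float("inf") if mean_after > 0 else 1.0
    changepoint = used[best].t_start
    chrom_end = max(w.t_end for w in windows)
    return BoundaryCall(
        changepoint_bp=int(changepoint),
        mean_before=mean_before,
        mean_after=mean_after,
        fold=float(fold),
        msy_interval=(int(changepoint), int(chrom_end)),
        no_transition=fold < fold_threshold,
        n_windows_used=n,
    )


# ---------------------------------------------------------------------------
# pipeline convenience


def align_chromosomes(
    x_sequence: str,
    y_sequence: str,
    k: int = 15,
    max_gap: int = 20_000,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[AlignmentChain]:
    """Full seed -> chain -> fill -> net route; returns netted chains."""
    anchors = seed_anchors(x_sequence, y_sequence, k)
    skeletons = chain_anchors(anchors, gap_open, gap_extend)
    filled = []
    for i, sk in enumerate(skeletons):
        ext = None
        if i == 0 and sk.strand == "+":
            ext = (0, len(y_sequence), 0, len(x_sequence))
        filled.append(
            fill_chain_gaps(
                sk, x_sequence, y_sequence, max_gap, extend_to=ext,
                match=match, mismatch=mismatch,
                gap_open=gap_open, gap_extend=gap_extend,
            )
        )
    return net_chains(filled)


def divergence_profile(
    x_sequence: str,
    y_sequence: str,
    window_bp: int = 10_000,
    step_bp: int | None = None,
    k: int = 15,
    max_gap: int = 20_000,
    min_cov: float = 0.25,
    min_windows_per_side: int = 5,
) -> tuple[list[AlignmentChain], list[WindowDivergence], BoundaryCall]:
    """Align, window, and call the PAR/MSY boundary in one step."""
    netted = align_chromosomes(x_sequence, y_sequence, k=k, max_gap=max_gap)
    windows = window_divergence(
        netted, window_bp=window_bp, step_bp=step_bp,
        chrom_length=len(y_sequence), min_cov=min_cov,
    )
    boundary = detect_boundary(windows, min_windows_per_side=min_windows_per_side)
    return netted, windows, boundary


# ---------------------------------------------------------------------------
# PAF interop (one line per block, cg:Z extended cigar)


_CIGAR_OP = {MATCH: "=", MISMATCH: "X", T_GAP: "I", Q_GAP: "D"}


def _cols_to_cigar(cols: np.ndarray) -> str:
    if len(cols) == 0:
        return ""
    brk = np.flatnonzero(np.diff(cols) != 0)
    bounds = np.concatenate([[0], brk + 1, [len(cols)]])
    return "".join(
        f"{bounds[i + 1] - bounds[i]}{_CIGAR_OP[int(cols[bounds[i]])]}"
        for i in range(len(bounds) - 1)
    )


def write_paf(
    chains: Sequence[AlignmentChain],
    path,
    q_name: str,
    t_name: str,
    q_len: int,
    t_len: int,
) -> None:
    with open(path, "w") as fh:
        for chain in chains:
            for b in chain.blocks:
                bc = np.bincount(b.cols, minlength=4)
                n_match = int(bc[MATCH])
                q_start, q_end = b.q_start, b.q_end
                if chain.strand == "-":
                    q_start, q_end = q_len - q_end, q_len - q_start
                fh.write(
                    "\t".join(
                        str(v)
                        for v in (
                            q_name, q_len, q_start, q_end, chain.strand,
                            t_name, t_len, b.t_start, b.t_end,
                            n_match, len(b.cols), 255,
                            f"cg:Z:{_cols_to_cigar(b.cols)}",
                        )
                    )
                    + "\n"
                )


_OP_CLASS = {"=": MATCH, "X": MISMATCH, "I": T_GAP, "D": Q_GAP}


def read_paf(path) -> list[AlignmentChain]:
    """Re-import chains written by :func:`write_paf` (one block per line)."""
    import re

    chains = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            q_len, q_start = int(f[1]), int(f[2])
            strand, t_start = f[4], int(f[7])
            cg = next(
                (tag[5:] for tag in f[12:] if tag.startswith("cg:Z:")), ""
            )
            parts = []
            for num, op in re.findall(r"(\d+)([=XID])", cg):
                parts.append(np.full(int(num), _OP_CLASS[op], dtype=np.uint8))
            cols = np.concatenate(parts) if parts else np.empty(0, np.uint8)
            qs = q_start if strand == "+" else q_len - int(f[3])
            block = Block(t_start, qs, cols)
            chains.append(
                AlignmentChain(
                    blocks=[block],
                    score=_score_cols(
                        cols, DEFAULT_MATCH, DEFAULT_MISMATCH,
                        DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND,
                    ),
                    strand=strand,
                )
            )
    chains.sort(key=lambda c: c.blocks[0].t_start)
    return chains
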