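"""Trio binning: classify long reads by parental origin with hap-mers.

A hap-mer is a canonical k-mer present in one parent's sequence data and
absent from the other's.  Each read is scored by its number of hits against
the two hap-mer sets; the larger count wins, ties (including 0-0) are
unclassified, and reads shorter than ``min_len`` are set aside.  Contig
assembly and coverage-based k-mer filtering are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "HapmerSet",
    "ReadAssignment",
    "BinSummary",
    "canonical",
    "sequence_kmers",
    "build_hapmer_sets",
    "classify_read",
    "bin_readset",
]

_RC = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_K = 21  # community standard for trio binning
DEFAULT_MIN_LEN = 1_000

LABELS = ("parentA", "parentB", "unclassified", "too_short")


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_RC)[::-1]
    return kmer if kmer <= rc else rc


def sequence_kmers(sequence: str, k: int) -> set[str]:
    """Canonical k-mers of a sequence; k-mers spanning an N are skipped."""
    seq = sequence.upper()
    out: set[str] = set()
    n = len(seq)
    # positions of ambiguous bases break the k-mer stream
    bad = [i for i, c in enumerate(seq) if c not in "ACGT"]
    segments = []
    prev = 0
    for b in bad:
        if b - prev >= k:
            segments.append((prev, b))
        prev = b + 1
    if n - prev >= k:
        segments.append((prev, n))
    for s, e in segments:
        sub = seq[s:e]
        rc = sub.translate(_RC)[::-1]
        m = len(sub) - k
        for i in range(m + 1):
            f = sub[i : i + k]
            r = rc[m - i : m - i + k]
            out.add(f if f <= r else r)
    return out


@dataclass(frozen=True)
class HapmerSet:
    parent_label: str
    k: int
    kmers: frozenset[str]

    def __post_init__(self):
        if self.k % 2 == 0 or not 15 <= self.k <= 31:
            raise ValueError("k must be odd and in [15, 31]")

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    label: str
    countA: int
    countB: int


def build_hapmer_sets(
    parentA_kmers: Iterable[str],
    parentB_kmers: Iterable[str],
    k: int,
    labels: tuple[str, str] = ("parentA", "parentB"),
) -> tuple[HapmerSet, HapmerSet]:
    """Parent-unique canonical k-mer sets (A \\ B and B \\ A).

    Inputs are k-mer collections (e.g. from :func:`sequence_kmers`); all
    k-mers must have length k.
    """
    a = {canonical(km.upper()) for km in parentA_kmers}
    b = {canonical(km.upper()) for km in parentB_kmers}
    if not a or not b:
        raise ValueError("both parental k-mer sets must be non-empty")
    for s in (a, b):
        bad = next((km for km in s if len(km) != k), None)
        if bad is not None:
            raise ValueError(f"k-mer {bad!r} does not match k={k}")
    return (
        HapmerSet(labels[0], k, frozenset(a - b)),
        HapmerSet(labels[1], k, frozenset(b - a)),
    )


def hapmer_sets_from_sequences(
    parentA_seqs: Iterable[str],
    parentB_seqs: Iterable[str],
    k: int = DEFAULT_K,
    labels: tuple[str, str] = ("parentA", "parentB"),
) -> tuple[HapmerSet, HapmerSet]:
    a: set[str] = set()
    for s in parentA_seqs:
        a |= sequence_kmers(s, k)
    b: set[str] = set()
    for s in parentB_seqs:
        b |= sequence_kmers(s, k)
    return build_hapmer_sets(a, b, k, labels)


def classify_read(
    read_id: str,
    read_sequence: str,
    hapA: HapmerSet,
    hapB: HapmerSet,
    min_len: int = DEFAULT_MIN_LEN,
) -> ReadAssignment:
    """Assign one read by majority of hap-mer hits; ties are unclassified."""
    if hapA.k != hapB.k:
        raise ValueError("hap-mer sets were built with different k")
    k = hapA.k
    if min_len < k:
        raise ValueError("min_len must be at least k")
    if len(read_sequence) < min_len:
        return ReadAssignment(read_id, "too_short", 0, 0)
    kmers = sequence_kmers(read_sequence, k)
    ca = len(kmers & hapA.kmers)
    cb = len(kmers & hapB.kmers)
    if ca > cb:
        label = "parentA"
    elif cb > ca:
        label = "parentB"
    else:
        label = "unclassified"
    return ReadAssignment(read_id, label, ca, cb)


@dataclass
class BinSummary:
    n_reads: dict[str, int]
    n_bases: dict[str, int]


def bin_readset(
    reads: Sequence[tuple[str, str]],
    hapA: HapmerSet,
    hapB: HapmerSet,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[dict[str, list[ReadAssignment]], BinSummary]:
    """Partition (read_id, sequence) pairs into the four bins.

    Every read lands in exactly one bin; the per-bin base totals sum to the
    input base total.
    """
    bins: dict[str, list[ReadAssignment]] = {label: [] for label in LABELS}
    n_bases = {label: 0 for label in LABELS}
    for read_id, seq in reads:
        a = classify_read(read_id, seq, hapA, hapB, min_len=min_len)
        bins[a.label].append(a)
        n_bases[a.label] += len(seq)
    summary = BinSummary(
        n_reads={label: len(v) for label, v in bins.items()}, n_bases=n_bases
    )
    return bins, summary
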