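"""Pooled-sequencing sex-specific SNP calling and windowed scan.

Input is a sync-like per-site allele-count table for a male pool and a
female pool.  A site is called male-specific when some allele sits at
frequency ~0.5 in the male pool (one Y-linked copy in XY males) and is
essentially absent from the female pool; female-specific sites are defined
symmetrically.  Counts and coverage are then summarized in 50 kb windows.
Read mapping and FST estimation are out of scope (the module consumes
counts).  Thresholds are conventions, not published values, and are
recorded in output headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SexSnpWindow",
    "call_sex_specific_snps",
    "window_sex_snp_scan",
    "write_sync",
    "read_sync",
]

_ALLELES = ("A", "C", "G", "T")
M_COLS = [f"m_{a}" for a in _ALLELES]
F_COLS = [f"f_{a}" for a in _ALLELES]


@dataclass
class SexSnpWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_sex_snps: int
    male_coverage_mean: float
    female_coverage_mean: float
    coverage_ratio: float  # M/F; nan when female coverage is 0
    flags: str  # "" | "low_coverage" | "no_ratio" (comma separated)


def call_sex_specific_snps(
    table: pd.DataFrame,
    min_depth: int = 10,
    het_band: float = 0.10,
    max_other: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Call male- and female-specific SNPs from pooled allele counts.

    A site is male-specific iff some allele has male-pool frequency within
    [0.5 - het_band, 0.5 + het_band] and female-pool frequency
    <= ``max_other``, with both pools at depth >= ``min_depth``
    (female-specific symmetrically).  Returns the called sites (columns:
    chrom, pos, ref, which, allele) and a QC dict counting sites skipped
    for low depth.
    """
    m = table[M_COLS].to_numpy(dtype=float)
    f = table[F_COLS].to_numpy(dtype=float)
    dm = m.sum(axis=1)
    df_ = f.sum(axis=1)
    ok = (dm >= min_depth) & (df_ >= min_depth)
    qc = {
        "n_sites": len(table),
        "n_low_depth_skipped": int((~ok).sum()),
        "min_depth": min_depth,
        "het_band": het_band,
        "max_other": max_other,
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        fm = np.where(dm[:, None] > 0, m / np.maximum(dm[:, None], 1), 0.0)
        ff = np.where(df_[:, None] > 0, f / np.maximum(df_[:, None], 1), 0.0)
    lo, hi = 0.5 - het_band, 0.5 + het_band
    male_specific = ok[:, None] & (fm >= lo) & (fm <= hi) & (ff <= max_other)
    female_specific = ok[:, None] & (ff >= lo) & (ff <= hi) & (fm <= max_other)

    rows = []
    for which, mask in (("male", male_specific), ("female", female_specific)):
        site_idx, allele_idx = np.nonzero(mask)
        for i, a in zip(site_idx, allele_idx):
            rows.append(
                (
                    table["chrom"].iat[i],
                    int(table["pos"].iat[i]),
                    table["ref"].iat[i],
                    which,
                    _ALLELES[a],
                )
            )
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "which", "allele"])
    sites = sites.drop_duplicates(subset=["chrom", "pos", "which"]).sort_values(
        ["chrom", "pos", "which"], kind="stable"
    )
    return sites.reset_index(drop=True), qc


def window_sex_snp_scan(
    sites: pd.DataFrame,
    table: pd.DataFrame,
    window_bp: int = 50_000,
    step_bp: int | None = None,
    which: str = "male",
    chrom_length: int | None = None,
    min_cov: float = 5.0,
) -> list[SexSnpWindow]:
    """Sex-SNP counts and pool coverage means per window.

    Windows tile the chromosome on 0-based coordinates (the sync table's
    1-based positions are converted internally).  Windows whose mean pool
    coverage falls below ``min_cov`` in either pool are flagged
    ``low_coverage``: an absence of sex SNPs there is not evidence of
    absence (e.g. mapping failure against a highly diverged terminus).
    """
    step = step_bp or window_bp
    chrom = table["chrom"].iat[0] if len(table) else "X"
    pos0 = table["pos"].to_numpy(dtype=np.int64) - 1
    order = np.argsort(pos0, kind="stable")
    pos0 = pos0[order]
    dm = table[M_COLS].to_numpy(dtype=float).sum(axis=1)[order]
    df_ = table[F_COLS].to_numpy(dtype=float).sum(axis=1)[order]

    sel = sites[sites["which"] == which] if len(sites) else sites
    spos = np.sort(sel["pos"].to_numpy(dtype=np.int64) - 1) if len(sel) else np.empty(0, np.int64)

    if chrom_length is None:
        chrom_length = int(pos0.max()) + 1 if len(pos0) else window_bp
    starts = np.arange(0, max(chrom_length - 1, 0) + 1, step, dtype=np.int64)
    starts = starts[starts < chrom_length]
    ends = np.minimum(starts + window_bp, chrom_length)

    out = []
    for s, e in zip(starts, ends):
        lo = np.searchsorted(pos0, s, side="left")
        hi = np.searchsorted(pos0, e, side="left")
        n_snp = int(
            np.searchsorted(spos, e, side="left") - np.searchsorted(spos, s, side="left")
        )
        cov_m = float(dm[lo:hi].mean()) if hi > lo else 0.0
        cov_f = float(df_[lo:hi].mean()) if hi > lo else 0.0
        flags = []
        if cov_m < min_cov or cov_f < min_cov:
            flags.append("low_coverage")
        if cov_f == 0:
            ratio = float("nan")
            flags.append("no_ratio")
        else:
            ratio = cov_m / cov_f
        out.append(
            SexSnpWindow(
                chrom=chrom,
                start=int(s),
                end=int(e),
                n_sex_snps=n_snp,
                male_coverage_mean=cov_m,
                female_coverage_mean=cov_f,
                coverage_ratio=ratio,
                flags=",".join(flags),
            )
        )
    return out


def pool_windows_frame(windows: Sequence[SexSnpWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sex_snps": [w.n_sex_snps for w in windows],
            "cov_m": [w.male_coverage_mean for w in windows],
            "cov_f": [w.female_coverage_mean for w in windows],
            "ratio": [w.coverage_ratio for w in windows],
            "flags": [w.flags for w in windows],
        }
    )


# ---------------------------------------------------------------------------
# sync-like I/O: chrom pos ref A:C:G:T:N:del per pool


def write_sync(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in table.iterrows():
            male = f"{r.m_A}:{r.m_C}:{r.m_G}:{r.m_T}:0:0"
            female = f"{r.f_A}:{r.f_C}:{r.f_G}:{r.f_T}:0:0"
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{male}\t{female}\n")


def read_sync(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, ref, male, female = line.split()[:5]
            ma = [int(x) for x in male.split(":")[:4]]
            fa = [int(x) for x in female.split(":")[:4]]
            rows.append((chrom, int(pos), ref, *ma, *fa))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", *M_COLS, *F_COLS]
    )
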