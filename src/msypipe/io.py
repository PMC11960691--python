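"""File-format helpers shared across the pipeline.

FASTA goes through Biopython.  BED and the pipeline's TSV tables are
written with a provenance header line (version, config hash, seed) so every
output file records how it was produced.  Coordinates are 0-based
half-open in BED and in memory; 1-based conventions (sync tables, GFF3)
are converted at the boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
    "write_tsv",
    "read_tsv",
    "provenance_header",
]


def provenance_header(config=None, extra: str = "") -> str:
    parts = [f"msypipe v{__version__}"]
    if config is not None:
        parts.append(f"config_hash={config.config_hash()}")
        parts.append(f"seed={config.seed}")
    if extra:
        parts.append(extra)
    return "# " + " ".join(parts)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    """Write sequences as 60-column wrapped FASTA."""
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


def write_bed(path, intervals: Sequence[tuple], config=None, extra: str = "") -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(provenance_header(config, extra) + "\n")
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return rows


def write_tsv(path, frame: pd.DataFrame, config=None, extra: str = "",
              float_format: str = "%.4f") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(provenance_header(config, extra) + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
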