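"""Readers and writers for the plain-text formats the pipeline touches.

``.pairs``-style read-pair text, BED peak/TSS intervals, BEDPE loop/interaction
output, TSV count tables, and a YAML config. Positions in ``.pairs`` files are
1-based (4DN convention) and converted once at ingest; every internal interval
is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

from loopdiff.genome import GenomeLayout

logger = logging.getLogger("loopdiff")

PAIRS_COLUMNS = (
    "readID",
    "chrom1",
    "pos1",
    "chrom2",
    "pos2",
    "strand1",
    "strand2",
    "mapq1",
    "mapq2",
)


@dataclass(frozen=True)
class PairRecord:
    """One read pair. Positions 0-based (converted from 1-based file coords)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str
    strand2: str
    mapq1: int
    mapq2: int

    @property
    def is_cis(self) -> bool:
        return self.chrom1 == self.chrom2


class PeakSet:
    """Sorted genomic intervals (0-based half-open) with optional name/score."""

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"PeakSet requires columns {sorted(required)}")
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def midpoints(self) -> pd.DataFrame:
        mid = (self.df["start"] + self.df["end"]) // 2
        return pd.DataFrame({"chrom": self.df["chrom"], "pos": mid})

    @classmethod
    def empty(cls) -> "PeakSet":
        return cls(
            pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "start": pd.Series(dtype=np.int64),
                    "end": pd.Series(dtype=np.int64),
                }
            )
        )


class AnnotationSet(PeakSet):
    """Intervals carrying a gene id (and optionally strand) — TSS records."""

    def __init__(self, df: pd.DataFrame):
        if "gene" not in df.columns:
            raise ValueError("AnnotationSet requires a 'gene' column")
        super().__init__(df)

    def tss_positions(self) -> pd.DataFrame:
        """One position per record: the interval start (TSS convention)."""
        return pd.DataFrame(
            {
                "chrom": self.df["chrom"],
                "pos": self.df["start"],
                "gene": self.df["gene"],
            }
        )


# ---------------------------------------------------------------- .pairs I/O


def read_pairs(
    path: str | Path, layout: GenomeLayout | None = None
) -> Iterator[PairRecord]:
    """Stream pair records from a ``.pairs``-style text file.

    Lines starting with ``#`` are header. Malformed lines and records on
    chromosomes absent from ``layout`` (or with out-of-range positions) are
    skipped with a logged count.
    """
    n_bad = n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 9:
                n_bad += 1
                logger.warning("malformed .pairs line %d: %r", lineno, line[:80])
                continue
            try:
                rec = PairRecord(
                    chrom1=parts[1],
                    pos1=int(parts[2]) - 1,
                    chrom2=parts[3],
                    pos2=int(parts[4]) - 1,
                    strand1=parts[5],
                    strand2=parts[6],
                    mapq1=int(parts[7]),
                    mapq2=int(parts[8]),
                )
            except ValueError:
                n_bad += 1
                logger.warning("unparseable .pairs line %d", lineno)
                continue
            if layout is not None:
                ok = (
                    rec.chrom1 in layout
                    and rec.chrom2 in layout
                    and 0 <= rec.pos1 < layout.length_of(rec.chrom1)
                    and 0 <= rec.pos2 < layout.length_of(rec.chrom2)
                )
                if not ok:
                    n_unknown += 1
                    continue
            yield rec
    if n_bad or n_unknown:
        logger.info(
            "read_pairs(%s): skipped %d malformed, %d out-of-layout records",
            path,
            n_bad,
            n_unknown,
        )


def write_pairs(records: Iterable[PairRecord], path: str | Path) -> int:
    """Write records as ``.pairs`` text (positions converted back to 1-based)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: " + " ".join(PAIRS_COLUMNS) + "\n")
        for rec in records:
            n += 1
            fh.write(
                f"r{n}\t{rec.chrom1}\t{rec.pos1 + 1}\t{rec.chrom2}\t{rec.pos2 + 1}"
                f"\t{rec.strand1}\t{rec.strand2}\t{rec.mapq1}\t{rec.mapq2}\n"
            )
    return n


# ------------------------------------------------------------------- BED I/O


def read_bed(path: str | Path, annotation: bool = False) -> PeakSet:
    """Read BED 3+ intervals; lines with start >= end are rejected with a log.

    With ``annotation=True`` column 4 is interpreted as a gene id and column 6
    (if present) as strand, yielding an :class:`AnnotationSet`.
    """
    rows = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                n_bad += 1
                continue
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                n_bad += 1
                logger.warning("BED line %d rejected: start >= end", lineno)
                continue
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) >= 4:
                row["name"] = parts[3]
            if len(parts) >= 5:
                try:
                    row["score"] = float(parts[4])
                except ValueError:
                    pass
            if len(parts) >= 6:
                row["strand"] = parts[5]
            rows.append(row)
    if not rows:
        df = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
            }
        )
        if annotation:
            df["gene"] = pd.Series(dtype=str)
            return AnnotationSet(df)
        return PeakSet(df)
    df = pd.DataFrame(rows)
    if annotation:
        df = df.rename(columns={"name": "gene"})
        return AnnotationSet(df)
    return PeakSet(df)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("name", "gene", "score", "strand"):
        if extra in peaks.df.columns:
            cols.append(extra)
    peaks.df[cols].to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------- BEDPE I/O


def write_bedpe(df: pd.DataFrame, path: str | Path) -> None:
    """Write anchor-pair records as BEDPE, sorted by chrom then anchor1 start.

    ``df`` must carry chrom1/start1/end1/chrom2/start2/end2; any further
    columns are appended in order.
    """
    anchor_cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    missing = [c for c in anchor_cols if c not in df.columns]
    if missing:
        raise ValueError(f"BEDPE output missing columns {missing}")
    extra = [c for c in df.columns if c not in anchor_cols]
    out = df.sort_values(["chrom1", "start1", "chrom2", "start2"]).reset_index(
        drop=True
    )
    out[anchor_cols + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bedpe(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------------- config


def read_config(path: str | Path) -> dict:
    """Parse the key-value (YAML) pipeline config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a key-value mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
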