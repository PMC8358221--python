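"""Shared file I/O: FASTA/FASTQ (plain or gzip), TSV tables, PAF/BED intervals.

Sequence parsing and writing go through Biopython; qualities are
Sanger/Phred+33. TSV files are tab-separated, UTF-8, unquoted; lines
starting with ``#`` are comments.
"""
from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .asmstats import DepthHistogram
from .chimera import ANCHOR_COLUMNS
from .readops import Read, ReadSet

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_anchor_table",
    "write_anchor_table",
    "read_depth_histogram",
    "write_depth_histogram",
    "read_bed_intervals",
    "read_paf_intervals",
    "write_json",
]

GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path, fmt: Optional[str] = None) -> ReadSet:
    """Parse FASTA or FASTQ (gzip auto-detected by magic bytes) into a ReadSet.

    Format is sniffed from the first character unless given; record ids are
    taken up to the first whitespace; FASTQ qualities are decoded Phred+33.
    Malformed records raise with the offending record named.
    """
    with _open_text(path) as fh:
        head = fh.read(1)
        if not head:
            raise ValueError(f"{path}: empty file")
        if fmt is None:
            if head == ">":
                fmt = "fasta"
            elif head == "@":
                fmt = "fastq"
            else:
                raise ValueError(f"{path}: cannot sniff format from leading {head!r}")
    records = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                qual = rec.letter_annotations.get("phred_quality")
                records.append(
                    Read(
                        rec.id,
                        str(rec.seq).upper(),
                        None if qual is None else np.asarray(qual, dtype=np.uint8),
                    )
                )
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed {fmt} near record {len(records) + 1}: {exc}"
            ) from exc
    return ReadSet(records)


def _to_seqrecords(reads, with_quality: bool):
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if with_quality:
            if r.qualities is None:
                raise ValueError(f"read {r.id!r} has no qualities; cannot write FASTQ")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        yield rec


def write_fasta(reads, path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(_to_seqrecords(reads, with_quality=False), fh, "fasta")


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(_to_seqrecords(reads, with_quality=True), fh, "fastq")


def write_anchor_table(table: pd.DataFrame, path) -> None:
    table.loc[:, ANCHOR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_anchor_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: anchor table missing columns {missing}")
    return df


def write_depth_histogram(hist: DepthHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("depth\tn_bases\n")
        for d in sorted(hist.bins):
            fh.write(f"{d}\t{hist.bins[d]}\n")


def read_depth_histogram(path) -> DepthHistogram:
    df = pd.read_csv(path, sep="\t", comment="#")
    return DepthHistogram(bins={int(d): int(n) for d, n in zip(df["depth"], df["n_bases"])})


def read_bed_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """BED (0-based half-open) -> {target: [(start, end), ...]}."""
    out: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return out


def read_paf_intervals(
    path, min_mapq: Optional[int] = None
) -> tuple[dict[str, list[tuple[int, int]]], dict[str, int]]:
    """PAF target-coordinate intervals plus target lengths.

    Optionally keeps only records with mapping quality >= ``min_mapq``
    (column 12).
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    lengths: dict[str, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            target, tlen, ts, te = p[5], int(p[6]), int(p[7]), int(p[8])
            if min_mapq is not None and int(p[11]) < min_mapq:
                continue
            lengths[target] = tlen
            intervals.setdefault(target, []).append((ts, te))
    return intervals, lengths


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
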