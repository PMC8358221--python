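"""Read-set statistics and manipulation.

This module houses the length statistics used throughout assembly QC
(Nx/Lx, mean, long-read fractions) and the three read-manipulation
procedures on which the design experiments are built: quality/length
filtering, length-preserving cutting ("C-series" read sets), and
coverage subsampling.

Conventions
-----------
* Nx is the length of the shortest sequence such that sequences of that
  length or longer hold at least x% of the total bases; Lx is the number
  of such sequences.
* Coordinates are 0-based half-open everywhere.
* Mean read quality averages per-base *error probabilities* and converts
  back to the Phred scale (ONT convention), not the arithmetic mean of Q.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Read",
    "ReadSet",
    "ReadLengthStats",
    "CutSpec",
    "nx",
    "nx_lx",
    "length_stats",
    "long_fraction",
    "mean_read_quality",
    "filter_reads",
    "cut_reads",
    "subsample_coverage",
]


@dataclass
class Read:
    """A single identified sequence with optional per-base Phred qualities."""

    id: str
    sequence: str
    qualities: Optional[np.ndarray] = None  # uint8 Phred scores, len == len(sequence)

    def __post_init__(self):
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, dtype=np.uint8)
            if self.qualities.shape != (len(self.sequence),):
                raise ValueError(
                    f"read {self.id!r}: quality length {self.qualities.size} "
                    f"!= sequence length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


class ReadSet:
    """An ordered collection of reads with unique ids.

    ``metadata`` carries provenance (e.g. the simulated ``error_rate`` or the
    true ``layout`` of simulated reads) and is propagated by the operations in
    this module.
    """

    def __init__(self, records: Iterable[Read], metadata: Optional[dict] = None):
        self.records: list[Read] = list(records)
        seen = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate read id {r.id!r}")
            seen.add(r.id)
        self.metadata: dict = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.records], dtype=np.int64)

    @property
    def total_bases(self) -> int:
        return int(self.lengths().sum()) if self.records else 0

    def __repr__(self) -> str:
        return f"ReadSet(n={len(self)}, bases={self.total_bases})"


@dataclass
class ReadLengthStats:
    """Summary of a read (or contig) length multiset."""

    n_reads: int
    total_bases: int
    mean: float
    nx: dict[int, int]  # percentage -> bases
    lx: dict[int, int]  # percentage -> count
    max: int

    @property
    def n50(self) -> int:
        return self.nx[50]

    @property
    def n90(self) -> int:
        return self.nx[90]


@dataclass(frozen=True)
class CutSpec:
    """Ordered cut offsets, e.g. (30000,) for C30, (20000, 20000) for C20+20."""

    offsets: tuple[int, ...]
    name: Optional[str] = None

    def __post_init__(self):
        if not self.offsets:
            raise ValueError("CutSpec needs at least one offset")
        if any(o < 1 for o in self.offsets):
            raise ValueError("all cut offsets must be >= 1")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        return "C" + "+".join(
            str(o // 1000) if o % 1000 == 0 else str(o) for o in self.offsets
        )


def _as_lengths(reads_or_lengths) -> np.ndarray:
    if isinstance(reads_or_lengths, ReadSet):
        lengths = reads_or_lengths.lengths()
    else:
        lengths = np.asarray(list(reads_or_lengths), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("empty length set")
    if (lengths < 1).any():
        raise ValueError("lengths must be >= 1")
    return lengths


def nx_lx(lengths, x: float) -> tuple[int, int]:
    """(Nx, Lx) of a length multiset.

    Nx is the smallest length L such that the summed length of all sequences
    >= L reaches x% of the total; Lx is how many such sequences there are.
    """
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    lengths = _as_lengths(lengths)
    srt = np.sort(lengths)[::-1]
    cum = np.cumsum(srt)
    need = x / 100.0 * cum[-1]
    idx = int(np.searchsorted(cum, need, side="left"))
    return int(srt[idx]), idx + 1


def nx(lengths, x: float) -> int:
    return nx_lx(lengths, x)[0]


def length_stats(reads_or_lengths, x_values: Sequence[int] = (10, 25, 50, 75, 90)) -> ReadLengthStats:
    """Full length-distribution summary (Nx/Lx at least at 50 and 90)."""
    lengths = _as_lengths(reads_or_lengths)
    xs = sorted(set(x_values) | {50, 90})
    nxd, lxd = {}, {}
    for x in xs:
        nxd[x], lxd[x] = nx_lx(lengths, x)
    total = int(lengths.sum())
    return ReadLengthStats(
        n_reads=int(lengths.size),
        total_bases=total,
        mean=total / lengths.size,
        nx=nxd,
        lx=lxd,
        max=int(lengths.max()),
    )


def long_fraction(lengths, threshold: int) -> tuple[float, float]:
    """Fraction of reads strictly longer than ``threshold`` and the fraction
    of total bases those reads contain."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    lengths = _as_lengths(lengths)
    mask = lengths > threshold
    return float(mask.mean()), float(lengths[mask].sum() / lengths.sum())


def mean_read_quality(read: Read) -> Optional[float]:
    """Phred-scaled mean quality: -10*log10(mean per-base error probability).

    Returns None for reads without quality strings.
    """
    if read.qualities is None:
        return None
    err = np.mean(10.0 ** (-read.qualities.astype(np.float64) / 10.0))
    return -10.0 * math.log10(err)


def filter_reads(reads: ReadSet, min_len: int = 0, min_q: float = 0.0) -> ReadSet:
    """Retain reads with length >= min_len and mean quality >= min_q.

    Both thresholds are inclusive; reads without qualities pass the quality
    filter (length evidence only).
    """
    if min_len < 0 or min_q < 0:
        raise ValueError("thresholds must be >= 0")
    kept = []
    for r in reads:
        if r.length < min_len:
            continue
        q = mean_read_quality(r)
        if q is not None and q < min_q:
            continue
        kept.append(r)
    return ReadSet(kept, metadata=reads.metadata)


def _cut_one(read: Read, offsets: Sequence[int]) -> list[Read]:
    frags: list[tuple[str, Optional[np.ndarray]]] = []
    seq, qual = read.sequence, read.qualities
    for off in offsets:
        if len(seq) > off:
            frags.append((seq[:off], None if qual is None else qual[:off]))
            seq = seq[off:]
            qual = None if qual is None else qual[off:]
        else:
            # remainder not strictly longer than the offset: left whole,
            # remaining offsets do not apply
            break
    frags.append((seq, qual))
    if len(frags) == 1:
        return [read]
    return [
        Read(f"{read.id}/{i + 1}", s, q) for i, (s, q) in enumerate(frags)
    ]


def cut_reads(reads: ReadSet, spec: CutSpec | Sequence[int]) -> ReadSet:
    """Split every read at the spec's successive offsets.

    Each offset removes a prefix fragment of that many bases when the current
    remainder is strictly longer than the offset (so no zero-length fragment
    can arise); all fragments are kept with suffixed ids and qualities are
    split in register. Total bases are conserved exactly.
    """
    if not isinstance(spec, CutSpec):
        spec = CutSpec(tuple(spec))
    out: list[Read] = []
    for r in reads:
        out.extend(_cut_one(r, spec.offsets))
    return ReadSet(out, metadata=reads.metadata)


def subsample_coverage(
    reads: ReadSet, genome_size: int, target_cov: float, seed: int
) -> ReadSet:
    """Seeded uniform subsample (without replacement) reaching a coverage target.

    Reads are shuffled and accumulated until total bases first reach
    ``target_cov * genome_size``; the overshoot is smaller than the last
    read's length.
    """
    if genome_size <= 0 or target_cov <= 0:
        raise ValueError("genome_size and target_cov must be > 0")
    target = target_cov * genome_size
    total = reads.total_bases
    if target > total:
        raise ValueError(
            f"insufficient bases for {target_cov:g}x: only "
            f"{total / genome_size:.2f}x available"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    lengths = reads.lengths()[order]
    k = int(np.searchsorted(np.cumsum(lengths), target, side="left")) + 1
    picked = [reads[int(i)] for i in order[:k]]
    return ReadSet(picked, metadata=reads.metadata)
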