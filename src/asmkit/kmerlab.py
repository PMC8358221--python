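"""k-mer counting and histogram analytics for genome-size and completeness work.

Counting is canonical (lexicographic minimum of a k-mer and its reverse
complement) and in-memory: k-mers are packed two bits per base into uint64
(k <= 31) and multiplicities obtained with a single sort, which comfortably
handles desk-scale inputs (tens of megabases). Inputs above a configurable
base budget are rejected outright rather than allowed to thrash.

The genome-size estimator follows the classic histogram recipe: total k-mer
instances above a noise threshold divided by the depth of the homozygous
peak. It assumes a haploid/homozygous sample (a doubled-haploid, say) —
heterozygous half-depth peaks are outside the default model and would
inflate the estimate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Union

import numpy as np
import pandas as pd

from ._encode import MAX_K, encode, window_codes
from .readops import Read, ReadSet

__all__ = [
    "KmerTable",
    "KmerHistogram",
    "SpectraCompMatrix",
    "NoiseThreshold",
    "GenomeSizeEstimate",
    "count_kmers",
    "histogram",
    "noise_threshold",
    "estimate_genome_size",
    "completeness",
    "spectra_comp",
]

DEFAULT_K = 21
#: refuse inputs above this many bases unless the caller raises the budget
DEFAULT_BASE_BUDGET = 200_000_000


@dataclass
class KmerTable:
    """Canonical k-mer multiplicities, stored as sorted packed codes."""

    k: int
    codes: np.ndarray  # sorted uint64
    counts: np.ndarray  # int64, parallel to codes

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def total_instances(self) -> int:
        return int(self.counts.sum()) if self.counts.size else 0

    def multiplicity(self, kmer: str) -> int:
        """Multiplicity of a k-mer given as a string (canonicalized)."""
        win, valid = window_codes(encode(kmer), self.k)
        if win.size != 1 or not valid[0]:
            raise ValueError(f"not a valid {self.k}-mer: {kmer!r}")
        i = int(np.searchsorted(self.codes, win[0]))
        if i < self.codes.size and self.codes[i] == win[0]:
            return int(self.counts[i])
        return 0

    def to_dict(self) -> dict[str, int]:
        """Decode to {kmer-string: multiplicity}; intended for small tables."""
        from ._encode import decode

        return {decode(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)}


@dataclass
class KmerHistogram:
    """multiplicity -> number of distinct k-mers."""

    k: int
    bins: dict[int, int]

    @property
    def total_instances(self) -> int:
        return sum(m * c for m, c in self.bins.items())

    @property
    def total_distinct(self) -> int:
        return sum(self.bins.values())


class NoiseThreshold(NamedTuple):
    multiplicity: int
    is_fallback: bool  # True when no local minimum exists (monotone histogram)


class GenomeSizeEstimate(NamedTuple):
    size: float
    peak_depth: float


@dataclass
class SpectraCompMatrix:
    """Read-multiplicity x assembly-copy-number decomposition (spectra-comp).

    ``matrix`` rows are read k-mer multiplicities; columns are assembly copy
    numbers 0, 1, ..., >=max_copy. Row sums reproduce the read histogram.
    """

    k: int
    matrix: pd.DataFrame

    def column_mass(self, copy: int, min_multiplicity: int = 1) -> int:
        rows = self.matrix.index >= min_multiplicity
        return int(self.matrix.loc[rows, copy].sum())


def _iter_sequences(sequences) -> Iterable[str]:
    if isinstance(sequences, str):
        yield sequences
    elif isinstance(sequences, Read):
        yield sequences.sequence
    elif isinstance(sequences, ReadSet):
        for r in sequences:
            yield r.sequence
    else:
        for s in sequences:
            yield s.sequence if isinstance(s, Read) else s


def count_kmers(
    sequences, k: int = DEFAULT_K, base_budget: int = DEFAULT_BASE_BUDGET
) -> KmerTable:
    """Canonical k-mer table of one or many sequences.

    k-mers containing non-ACGT symbols are skipped. Raises if k exceeds every
    sequence's length or the total input exceeds ``base_budget`` bases.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    chunks = []
    total = 0
    longest = 0
    n_seq = 0
    for seq in _iter_sequences(sequences):
        n_seq += 1
        total += len(seq)
        longest = max(longest, len(seq))
        if total > base_budget:
            raise ValueError(
                f"input exceeds the in-memory base budget ({base_budget} bases); "
                "raise base_budget explicitly for larger inputs"
            )
        if len(seq) < k:
            continue
        win, valid = window_codes(encode(seq), k)
        chunks.append(win[valid])
    if n_seq == 0:
        raise ValueError("no input sequences")
    if longest < k:
        raise ValueError(f"k={k} is longer than every input sequence (max {longest})")
    if not chunks:
        codes = np.empty(0, dtype=np.uint64)
        counts = np.empty(0, dtype=np.int64)
    else:
        codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return KmerTable(k=k, codes=codes, counts=counts.astype(np.int64))


def histogram(table: KmerTable) -> KmerHistogram:
    """Histogram of multiplicities: bins[m] = distinct k-mers seen m times."""
    if table.n_distinct == 0:
        raise ValueError("empty k-mer table")
    mult, cnt = np.unique(table.counts, return_counts=True)
    return KmerHistogram(k=table.k, bins={int(m): int(c) for m, c in zip(mult, cnt)})


def _dense_bins(hist: KmerHistogram) -> np.ndarray:
    mmax = max(hist.bins)
    dense = np.zeros(mmax + 1, dtype=np.int64)
    for m, c in hist.bins.items():
        dense[m] = c
    return dense


def noise_threshold(hist: KmerHistogram) -> NoiseThreshold:
    """First local minimum of the histogram scanning multiplicity upward.

    Separates the error-k-mer slope from the genomic peak. If the histogram
    has no local minimum (monotone decreasing), returns multiplicity 1 with
    the fallback flag set.
    """
    if len(hist.bins) < 3:
        raise ValueError("histogram needs at least 3 occupied bins")
    dense = _dense_bins(hist)
    lo = min(hist.bins)
    for m in range(lo, dense.size - 1):
        if dense[m] < dense[m + 1]:
            return NoiseThreshold(multiplicity=max(m, 1), is_fallback=False)
    return NoiseThreshold(multiplicity=1, is_fallback=True)


def estimate_genome_size(
    hist: KmerHistogram,
    threshold: int | NoiseThreshold | None = None,
    refine: bool = True,
) -> GenomeSizeEstimate:
    """Histogram genome-size estimate: solid k-mer instances / peak depth.

    ``threshold`` (default: ``noise_threshold(hist)``) excludes the error
    slope; the peak is the most populated multiplicity at or above it. With
    ``refine=True`` the peak depth is sharpened to the local mass centroid of
    the bins within +/-20% of the argmax, removing the up-to-1/peak bias a
    bare integer argmax carries when the true depth falls between integers.
    """
    if threshold is None:
        threshold = noise_threshold(hist)
    if isinstance(threshold, NoiseThreshold):
        threshold = threshold.multiplicity
    dense = _dense_bins(hist)
    if threshold >= dense.size:
        raise ValueError("no histogram bins at or above the threshold")
    m = np.arange(dense.size)
    solid = m >= threshold
    if not dense[solid].any():
        raise ValueError("no histogram bins at or above the threshold")
    peak = int(m[solid][np.argmax(dense[solid])])
    peak_depth = float(peak)
    if refine:
        # histogram counts are spatially correlated along the genome, so the
        # raw argmax is noisy: smooth lightly, then iterate the mass centroid
        # of a +/-20% window to its fixed point
        w = min(5, dense.size if dense.size % 2 else dense.size - 1)
        w = max(w, 1)
        sm = np.convolve(dense.astype(float), np.ones(w) / w, mode="same")
        sm[: threshold] = 0.0
        peak_depth = float(m[solid][np.argmax(sm[solid])])
        for _ in range(50):
            lo = max(threshold, int(round(peak_depth * 0.8)))
            hi = min(dense.size - 1, int(round(peak_depth * 1.2)))
            w = dense[lo : hi + 1].astype(float)
            if w.sum() <= 0:
                break
            new = float(np.average(np.arange(lo, hi + 1), weights=w))
            if abs(new - peak_depth) < 1e-3:
                peak_depth = new
                break
            peak_depth = new
    instances = float((m[solid] * dense[solid]).sum())
    return GenomeSizeEstimate(size=instances / peak_depth, peak_depth=peak_depth)


def _require_same_k(a: KmerTable, b: KmerTable):
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")


def completeness(
    read_table: KmerTable, assembly_table: KmerTable, threshold: int | NoiseThreshold = 1
) -> float:
    """Fraction of solid read k-mers (multiplicity >= threshold) present in
    the assembly."""
    _require_same_k(read_table, assembly_table)
    if isinstance(threshold, NoiseThreshold):
        threshold = threshold.multiplicity
    solid = read_table.codes[read_table.counts >= threshold]
    if solid.size == 0:
        raise ValueError("no solid read k-mers at this threshold")
    if assembly_table.n_distinct == 0:
        return 0.0
    idx = np.searchsorted(assembly_table.codes, solid)
    idx = np.minimum(idx, assembly_table.n_distinct - 1)
    present = assembly_table.codes[idx] == solid
    return float(present.mean())


def spectra_comp(
    read_table: KmerTable, assembly_table: KmerTable, max_copy: int = 4
) -> SpectraCompMatrix:
    """Decompose the read k-mer histogram by assembly copy number.

    The 0x column above the noise threshold quantifies sequence missing from
    the assembly; enrichment of the >=2x columns at multiples of the main
    peak reflects how repeats are represented.
    """
    _require_same_k(read_table, assembly_table)
    if max_copy < 1:
        raise ValueError("max_copy must be >= 1")
    # assembly copy number of every distinct read k-mer (0 when absent)
    if assembly_table.n_distinct:
        idx = np.searchsorted(assembly_table.codes, read_table.codes)
        idx_c = np.minimum(idx, assembly_table.n_distinct - 1)
        hit = assembly_table.codes[idx_c] == read_table.codes
        copy = np.where(hit, assembly_table.counts[idx_c], 0)
    else:
        copy = np.zeros(read_table.n_distinct, dtype=np.int64)
    copy = np.minimum(copy, max_copy)
    mult = read_table.counts
    mults = np.unique(mult)
    mat = np.zeros((mults.size, max_copy + 1), dtype=np.int64)
    row_of = {int(v): i for i, v in enumerate(mults)}
    flat = np.searchsorted(mults, mult) * (max_copy + 1) + copy
    binc = np.bincount(flat, minlength=mults.size * (max_copy + 1))
    mat[:, :] = binc.reshape(mults.size, max_copy + 1)
    df = pd.DataFrame(mat, index=[int(v) for v in mults], columns=list(range(max_copy + 1)))
    df.index.name = "read_multiplicity"
    return SpectraCompMatrix(k=read_table.k, matrix=df)
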