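"""Synthetic genomes, read sets, depth histograms, and gene-anchor tables.

The generator emulates the statistical structure the downstream analyses
assume for a repeat-rich plant genome sequenced with ultralong nanopore
reads:

* genomes with parameterized repeat families planted at random
  non-overlapping positions (repeats are abstract units, not TE models);
* read sets with a log-normal length distribution fitted to a target
  mean/N50 (the distribution family of real ONT runs is not knowable from
  mean and N50 alone; the log-normal is a stand-in, not a claim);
* per-base depth histograms as Poisson mixtures with optional allelic
  (0.5x) and collapsed (2x) components;
* gene-anchor tables with engineered chimeric joins.

All randomness flows from a single integer seed per call; identical
specs + seeds give byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .readops import Read, ReadSet

__all__ = [
    "GenomeSpec",
    "LengthModel",
    "DepthMixtureSpec",
    "simulate_genome",
    "mutate_haplotype",
    "fit_length_model",
    "simulate_reads",
    "simulate_depth_histogram",
    "simulate_anchor_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint of a synthetic haploid genome.

    ``repeat_families`` is a list of ``(unit_length, copy_count, divergence)``
    tuples; each family is planted as ``copy_count`` near-identical copies of
    one random unit, every copy independently mutated at ``divergence``
    substitutions/base.
    """

    length: int
    repeat_families: tuple[tuple[int, int, float], ...] = ()
    gc: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("genome length must be > 0")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        object.__setattr__(self, "repeat_families", tuple(tuple(f) for f in self.repeat_families))
        total = 0
        for unit, copies, div in self.repeat_families:
            if unit < 1 or copies < 1:
                raise ValueError("repeat unit_length and copy_count must be >= 1")
            if not 0 <= div < 1:
                raise ValueError("divergence must be in [0, 1)")
            total += unit * copies
            if total > self.length:
                raise ValueError(
                    f"repeat family (unit={unit}, copies={copies}) overfills the "
                    f"genome: {total} repeat bases > length {self.length}"
                )


@dataclass(frozen=True)
class LengthModel:
    """Log-normal read-length model; sigma == 0 degenerates to constant length."""

    mu: float
    sigma: float
    min_length: int = 1

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")

    @property
    def mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)

    @property
    def n50(self) -> float:
        """Base-weighted median, the large-n N50 of the model."""
        return math.exp(self.mu + self.sigma**2)


@dataclass(frozen=True)
class DepthMixtureSpec:
    """Poisson depth mixture: primary peak plus optional allelic (0.5x) and
    collapsed (2x) components holding the given base fractions."""

    primary_depth: float
    allelic_fraction: float = 0.0
    collapsed_fraction: float = 0.0
    n_bases: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.primary_depth <= 0:
            raise ValueError("primary_depth must be > 0")
        for f in (self.allelic_fraction, self.collapsed_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.allelic_fraction + self.collapsed_fraction > 1:
            raise ValueError("component fractions sum to more than 1")
        if self.n_bases <= 0:
            raise ValueError("n_bases must be > 0 (empty histograms fail fast)")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a different base)."""
    if rate <= 0:
        return arr.copy()
    out = arr.copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # map base -> one of the three others, chosen uniformly
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + shift) % 4]
    return out


def simulate_genome(spec: GenomeSpec) -> str:
    """Deterministic (seeded) genome of exactly ``spec.length`` bases.

    Repeat copies are planted at uniformly drawn non-overlapping positions;
    the remainder is i.i.d. with the requested GC.
    """
    rng = np.random.default_rng(spec.seed)
    genome = _random_bases(rng, spec.length, spec.gc)
    placed: list[tuple[int, int]] = []  # occupied [start, end)
    for fam_i, (unit_len, copies, div) in enumerate(spec.repeat_families):
        unit = _random_bases(rng, unit_len, spec.gc)
        for _ in range(copies):
            for attempt in range(10_000):
                start = int(rng.integers(0, spec.length - unit_len + 1))
                end = start + unit_len
                if all(end <= s or start >= e for s, e in placed):
                    break
            else:
                raise ValueError(
                    f"could not place repeat family #{fam_i} "
                    f"(unit={unit_len}, copies={copies}): genome too crowded"
                )
            placed.append((start, end))
            genome[start:end] = _mutate(rng, unit, div)
    return genome.tobytes().decode("ascii")


def mutate_haplotype(genome: str, het_rate: float, seed: int) -> str:
    """Same-length sequence differing at ~het_rate * length positions."""
    if not 0 <= het_rate < 1:
        raise ValueError("het_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    return _mutate(rng, arr, het_rate).tobytes().decode("ascii")


def fit_length_model(
    target_mean: float, target_n50: float, min_length: int = 1
) -> LengthModel:
    """Closed-form log-normal fit to a target mean and N50.

    Uses the base-weighted median as the N50 surrogate (exact in the large-n
    limit): mean = exp(mu + sigma^2/2) and N50 = exp(mu + sigma^2), whence
    sigma^2 = 2*ln(n50/mean) and mu = ln(mean) - sigma^2/2. A target N50
    equal to the mean returns the sigma=0 constant-length model; below the
    mean there is no log-normal solution.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be > 0")
    if target_n50 < target_mean:
        raise ValueError(
            "no log-normal solution: target_n50 must be >= target_mean "
            f"(got mean={target_mean}, n50={target_n50})"
        )
    sigma2 = 2.0 * math.log(target_n50 / target_mean)
    return LengthModel(
        mu=math.log(target_mean) - sigma2 / 2,
        sigma=math.sqrt(sigma2),
        min_length=min_length,
    )


def _phred_char_array(q: int, n: int) -> np.ndarray:
    return np.full(n, q, dtype=np.uint8)


def simulate_reads(
    genome: str,
    model: LengthModel,
    coverage: float,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Reads at uniform start positions, lengths drawn from ``model``.

    Lengths are floored at ``model.min_length`` and truncated at the genome
    end; reads accumulate until total bases first reach
    ``coverage * len(genome)``. With ``error_rate`` 0 every read is an exact
    substring of the genome (forward strand). Constant per-base qualities are
    emitted consistent with the error rate.

    The true layout is recorded in ``metadata["layout"]`` as id -> (start, end)
    and the error rate in ``metadata["error_rate"]``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0 (empty requests fail fast)")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    glen = len(genome)
    if glen < model.min_length:
        raise ValueError(
            f"genome ({glen} bases) shorter than model.min_length ({model.min_length})"
        )
    rng = np.random.default_rng(seed)
    q = 90 if error_rate == 0 else max(1, round(-10 * math.log10(error_rate)))
    target = coverage * glen
    garr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    records: list[Read] = []
    layout: dict[str, tuple[int, int]] = {}
    total = 0
    i = 0
    while total < target:
        n_draw = max(16, int((target - total) / max(model.mean, 1)) + 8)
        if model.sigma == 0:
            lens = np.full(n_draw, round(math.exp(model.mu)))
        else:
            lens = rng.lognormal(model.mu, model.sigma, size=n_draw)
        lens = np.maximum(np.rint(lens).astype(np.int64), model.min_length)
        starts = rng.integers(0, glen, size=n_draw)
        for L, s in zip(lens, starts):
            e = min(int(s) + int(L), glen)
            if e <= s:
                continue
            i += 1
            rid = f"read_{i:07d}"
            sub = garr[s:e]
            if error_rate > 0:
                sub = _mutate(rng, sub, error_rate)
            records.append(
                Read(rid, sub.tobytes().decode("ascii"), _phred_char_array(q, e - int(s)))
            )
            layout[rid] = (int(s), e)
            total += e - int(s)
            if total >= target:
                break
    return ReadSet(records, metadata={"error_rate": error_rate, "layout": layout})


def simulate_depth_histogram(spec: DepthMixtureSpec):
    """Depth histogram sampled from the three-component Poisson mixture."""
    from .asmstats import DepthHistogram

    rng = np.random.default_rng(spec.seed)
    n_allelic = int(round(spec.allelic_fraction * spec.n_bases))
    n_collapsed = int(round(spec.collapsed_fraction * spec.n_bases))
    n_primary = spec.n_bases - n_allelic - n_collapsed
    depths = np.concatenate(
        [
            rng.poisson(spec.primary_depth, n_primary),
            rng.poisson(0.5 * spec.primary_depth, n_allelic),
            rng.poisson(2.0 * spec.primary_depth, n_collapsed),
        ]
    )
    counts = np.bincount(depths)
    bins = {int(d): int(c) for d, c in enumerate(counts) if c > 0}
    return DepthHistogram(bins=bins)


_CHROMS = tuple(f"chr{i}" for i in range(1, 8))


def simulate_anchor_table(
    n_contigs: int,
    genes_per_contig: int,
    chimera_spec: Sequence[tuple[int | str, int, int]] = (),
    seed: int = 0,
    gene_spacing: int = 20_000,
) -> pd.DataFrame:
    """Gene-anchor table (contig, gene_index, position, chromosome).

    Every contig's genes are assigned one majority chromosome; each
    ``(contig, start_gene_index, run_length)`` entry in ``chimera_spec``
    reassigns that run of consecutive genes to a different chromosome,
    engineering a chimeric join. Overlapping insertions are rejected.
    """
    if n_contigs < 1 or genes_per_contig < 1:
        raise ValueError("n_contigs and genes_per_contig must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"contig_{i + 1}" for i in range(n_contigs)]
    majors = {name: _CHROMS[int(rng.integers(0, len(_CHROMS)))] for name in names}
    chrom_of: dict[str, list[str]] = {name: [majors[name]] * genes_per_contig for name in names}
    used: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    for contig, start, run_length in chimera_spec:
        name = names[contig] if isinstance(contig, int) else str(contig)
        if name not in chrom_of:
            raise ValueError(f"unknown contig {name!r} in chimera_spec")
        if run_length < 1:
            raise ValueError("run_length must be >= 1")
        if not 0 <= start <= genes_per_contig - run_length:
            raise ValueError(
                f"chimera run [{start}, {start + run_length}) outside the "
                f"gene-order range of {name}"
            )
        for s, e in used[name]:
            if start < e and s < start + run_length:
                raise ValueError(f"overlapping chimera insertions on {name}")
        used[name].append((start, start + run_length))
        major = majors[name]
        other = _CHROMS[(_CHROMS.index(major) + 1) % len(_CHROMS)]
        for g in range(start, start + run_length):
            chrom_of[name][g] = other
    rows = []
    for name in names:
        pos = 0
        for g in range(genes_per_contig):
            pos += int(rng.integers(gene_spacing // 2, 3 * gene_spacing // 2))
            rows.append((name, g, pos, chrom_of[name][g]))
    return pd.DataFrame(rows, columns=["contig", "gene_index", "position", "chromosome"])
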