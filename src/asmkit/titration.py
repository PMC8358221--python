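"""Coverage-titration and cut-read experiments with a pluggable assembler.

The two in-silico design experiments ask how assembly contiguity responds
to (a) input coverage and (b) input read length at constant bases. Both
feed an assembler; the built-in one is a deliberately small greedy
suffix-prefix unitigger for *error-free* reads: it removes contained
reads, finds exact overlaps via packed-seed lookup, and extends only
through mutually unique maximal overlaps (best buddies on both ends).
Repeats longer than the spanned overlap therefore break contigs,
which is exactly the phenomenology the experiments probe. Real assemblers
can be registered through the same callable contract (ReadSet -> ReadSet).

The saturation of contig N50 with coverage is summarized by the
two-parameter exponential N50(c) = n_max * (1 - exp(-c / tau)); the
coverage where the curve reaches a fraction f of its asymptote is
c = -tau * ln(1 - f).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._encode import encode, window_codes
from .asmstats import AssemblyStats, contig_stats
from .readops import CutSpec, Read, ReadSet, cut_reads, subsample_coverage

__all__ = [
    "TitrationTable",
    "SaturationFit",
    "SaturationFitError",
    "greedy_assemble",
    "run_titration",
    "run_cut_series",
    "fit_saturation",
    "coverage_at_fraction",
]

Assembler = Callable[[ReadSet], ReadSet]


@dataclass
class TitrationTable:
    """Per-coverage assembly statistics plus run provenance."""

    rows: pd.DataFrame  # columns: coverage, n50, n90, total, n_contigs
    metadata: dict

    @property
    def coverages(self) -> np.ndarray:
        return self.rows["coverage"].to_numpy(dtype=float)

    @property
    def n50s(self) -> np.ndarray:
        return self.rows["n50"].to_numpy(dtype=float)


@dataclass
class SaturationFit:
    n_max: float
    tau: float
    rss: float
    n_points: int
    model: str = "exponential"

    def predict(self, coverage) -> np.ndarray:
        c = np.asarray(coverage, dtype=float)
        if self.model == "exponential":
            return self.n_max * (1.0 - np.exp(-c / self.tau))
        return self.n_max * c / (self.tau + c)


class SaturationFitError(RuntimeError):
    def __init__(self, msg, p0=None, residuals=None):
        super().__init__(msg)
        self.p0 = p0
        self.residuals = residuals


# ---------------------------------------------------------------------------
# toy greedy-overlap assembler
# ---------------------------------------------------------------------------


def _dedupe_and_index(reads: ReadSet):
    """Drop exact duplicate sequences (keep the first id)."""
    seen: dict[bytes, int] = {}
    keep: list[tuple[str, bytes]] = []
    for r in reads:
        b = r.sequence.encode("ascii")
        if b not in seen:
            seen[b] = len(keep)
            keep.append((r.id, b))
    return keep


def greedy_assemble(reads: ReadSet, min_overlap: int = 100) -> ReadSet:
    """Greedy exact-overlap unitigger for error-free reads.

    Contained reads are removed; exact suffix-prefix overlaps of at least
    ``min_overlap`` bases are located by packed-seed lookup and verified by
    string comparison. Unitigs follow mutually unique maximal overlaps: read
    i joins read j only when j is i's single best right partner and i is j's
    single best left partner; any tie (>= 2 equally maximal candidates, the
    signature of a repeat boundary) halts extension, so repeats longer than
    the spanned overlap break contigs while reads that span a repeat carry
    straight through. Deterministic given input order; ties broken by read
    id.
    """
    if len(reads) == 0:
        raise ValueError("empty read set")
    if reads.metadata.get("error_rate", 0) > 0:
        raise ValueError(
            "greedy_assemble requires error-free reads (exact-match overlaps); "
            f"this read set was simulated with error_rate="
            f"{reads.metadata['error_rate']}"
        )
    if min_overlap < 20:
        raise ValueError("min_overlap must be >= 20")

    entries = _dedupe_and_index(reads)
    n = len(entries)
    ids = [e[0] for e in entries]
    seqs = [e[1] for e in entries]
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    s = min(min_overlap, 31)

    # concatenate with a separator so windows never straddle two reads
    sep = b"N"
    concat = sep.join(seqs)
    starts = np.zeros(n, dtype=np.int64)
    off = 0
    for i, L in enumerate(lens):
        starts[i] = off
        off += int(L) + 1
    win, valid = window_codes(encode(concat), s, canonical=False)

    too_short = lens < s
    prefix_codes = np.where(~too_short, win[np.minimum(starts, win.size - 1)], 0)
    pref_map: dict[int, list[int]] = {}
    for i in range(n):
        if too_short[i]:
            continue
        pref_map.setdefault(int(prefix_codes[i]), []).append(i)

    uniq_pref = np.unique(prefix_codes[~too_short]) if (~too_short).any() else np.empty(0, np.uint64)
    cand_pos = np.nonzero(valid & np.isin(win, uniq_pref))[0]

    contained = np.zeros(n, dtype=bool)
    overlaps: dict[int, dict[int, int]] = {i: {} for i in range(n)}  # i -> {j: o}
    for g in cand_pos:
        i = int(np.searchsorted(starts, g, side="right")) - 1
        p = int(g - starts[i])
        if p > lens[i] - s:  # window crosses the separator
            continue
        for j in pref_map.get(int(win[g]), ()):
            if i == j:
                continue
            o = int(lens[i]) - p
            if o >= lens[j]:
                # candidate containment of j inside i
                if seqs[i][p : p + int(lens[j])] == seqs[j]:
                    contained[j] = True
                continue
            if o < min_overlap:
                continue
            if seqs[i][p:] == seqs[j][:o]:
                prev = overlaps[i].get(j)
                if prev is None or o > prev:
                    overlaps[i][j] = o

    # mutual best-buddy joins: i -> j only when j is i's unique
    # maximal-overlap right partner AND i is j's unique maximal-overlap left
    # partner; any tie is a branch and halts extension there
    right_best: dict[int, tuple[int, int]] = {}  # i -> (j, o)
    incoming: dict[int, list[tuple[int, int]]] = {}  # j -> [(o, i), ...]
    for i in range(n):
        if contained[i]:
            continue
        cands = [(o, j) for j, o in overlaps[i].items() if not contained[j]]
        if not cands:
            continue
        for o, j in cands:
            incoming.setdefault(j, []).append((o, i))
        omax = max(o for o, _ in cands)
        top = [j for o, j in cands if o == omax]
        if len(top) == 1:
            right_best[i] = (top[0], omax)

    joins: dict[int, tuple[int, int]] = {}
    for i, (j, o) in right_best.items():
        inc = incoming[j]
        imax = max(oo for oo, _ in inc)
        left_top = [ii for oo, ii in inc if oo == imax]
        if len(left_top) == 1 and left_top[0] == i:
            joins[i] = (j, o)

    has_incoming = {jo[0] for jo in joins.values()}
    visited = np.zeros(n, dtype=bool)
    contigs: list[bytes] = []

    def walk(start: int):
        parts = [seqs[start]]
        visited[start] = True
        cur = start
        while cur in joins:
            j, o = joins[cur]
            if visited[j]:
                break  # cycle guard
            parts.append(seqs[j][o:])
            visited[j] = True
            cur = j
        contigs.append(b"".join(parts))

    order = sorted(range(n), key=lambda i: ids[i])
    for i in order:
        if not contained[i] and not visited[i] and i not in has_incoming:
            walk(i)
    for i in order:  # anything left is on a cycle
        if not contained[i] and not visited[i]:
            walk(i)

    out = [
        Read(f"ctg_{k + 1:05d}", c.decode("ascii"))
        for k, c in enumerate(sorted(contigs, key=len, reverse=True))
    ]
    return ReadSet(out, metadata={"assembler": "greedy", "min_overlap": min_overlap})


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def run_titration(
    reads: ReadSet,
    genome_size: int,
    coverages: Sequence[float],
    assembler: Optional[Assembler] = None,
    seed: int = 0,
    nested: bool = True,
    min_overlap: int = 100,
) -> TitrationTable:
    """Assemble coverage subsets and tabulate contiguity per coverage.

    With ``nested=True`` (default) lower-coverage subsets are prefixes of the
    higher ones (one seeded shuffle), which removes between-row sampling
    variance; independent subsampling per row is available with
    ``nested=False``.
    """
    coverages = list(coverages)
    if any(b <= a for a, b in zip(coverages, coverages[1:])):
        raise ValueError("coverages must be strictly increasing")
    assembler_id = "greedy" if assembler is None else getattr(assembler, "__name__", "custom")
    if assembler is None:
        assembler = lambda rs: greedy_assemble(rs, min_overlap=min_overlap)
    rows = []
    for step, cov in enumerate(coverages):
        try:
            sub = subsample_coverage(
                reads, genome_size, cov, seed=seed if nested else seed + step
            )
            contigs = assembler(sub)
            st = contig_stats(contigs)
        except Exception as exc:
            raise RuntimeError(f"titration failed at coverage {cov}x: {exc}") from exc
        rows.append(
            dict(coverage=cov, n50=st.n50, n90=st.n90, total=st.total, n_contigs=st.n_sequences)
        )
    df = pd.DataFrame(rows)
    return TitrationTable(rows=df, metadata={"assembler": assembler_id, "seed": seed, "nested": nested})


def run_cut_series(
    reads: ReadSet,
    specs: Sequence[CutSpec],
    assembler: Optional[Assembler] = None,
    min_overlap: int = 100,
) -> pd.DataFrame:
    """Assemble the uncut baseline and every cut variant of one read set.

    Cutting preserves total bases, so every row sees identical input bases —
    this is enforced, not assumed. Columns: label, n_reads, input_bases,
    n_contigs, total, n50, n90.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if assembler is None:
        assembler = lambda rs: greedy_assemble(rs, min_overlap=min_overlap)
    baseline_bases = reads.total_bases
    rows = []
    variants: list[tuple[str, ReadSet]] = [("uncut", reads)]
    for spec in specs:
        if not isinstance(spec, CutSpec):
            spec = CutSpec(tuple(spec))
        variants.append((spec.label, cut_reads(reads, spec)))
    for label, rs in variants:
        if rs.total_bases != baseline_bases:
            raise RuntimeError(
                f"base conservation violated for {label}: "
                f"{rs.total_bases} != {baseline_bases}"
            )
        contigs = assembler(rs)
        st = contig_stats(contigs)
        rows.append(
            dict(
                label=label,
                n_reads=len(rs),
                input_bases=rs.total_bases,
                n_contigs=st.n_sequences,
                total=st.total,
                n50=st.n50,
                n90=st.n90,
            )
        )
    return pd.DataFrame(rows)


def fit_saturation(table, model: str = "exponential") -> SaturationFit:
    """Least-squares fit of the N50-vs-coverage saturation curve.

    Accepts a TitrationTable or ``(coverages, n50s)`` arrays. The default
    model is N50(c) = n_max*(1 - exp(-c/tau)); ``model="mm"`` fits the
    Michaelis-Menten alternative n_max*c/(K+c) (tau then plays K's role).
    Initialization: n_max = 1.1 * max observed N50, tau = coverage at
    half-max / ln 2.
    """
    if isinstance(table, TitrationTable):
        c, y = table.coverages, table.n50s
    else:
        c, y = (np.asarray(v, dtype=float) for v in table)
    if c.size < 3:
        raise ValueError("need at least 3 titration points to fit")
    nmax0 = 1.1 * float(y.max())
    half_idx = int(np.argmax(y >= 0.5 * y.max()))
    tau0 = max(float(c[half_idx]) / math.log(2), 1e-6)
    if model == "exponential":
        f = lambda cc, nmax, tau: nmax * (1.0 - np.exp(-cc / tau))
    elif model == "mm":
        f = lambda cc, nmax, K: nmax * cc / (K + cc)
    else:
        raise ValueError(f"unknown saturation model {model!r}")
    try:
        popt, _ = curve_fit(
            f, c, y, p0=(nmax0, tau0), bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=20_000
        )
    except RuntimeError as exc:
        resid = y - f(c, nmax0, tau0)
        raise SaturationFitError(
            f"saturation fit did not converge: {exc}", p0=(nmax0, tau0), residuals=resid
        ) from exc
    resid = y - f(c, *popt)
    return SaturationFit(
        n_max=float(popt[0]),
        tau=float(popt[1]),
        rss=float(np.sum(resid**2)),
        n_points=int(c.size),
        model=model,
    )


def coverage_at_fraction(fit: SaturationFit, f: float) -> float:
    """Coverage at which the fitted curve reaches fraction ``f`` of n_max."""
    if not 0 < f < 1:
        raise ValueError("f must be in (0, 1)")
    if fit.model == "exponential":
        return -fit.tau * math.log(1.0 - f)
    return fit.tau * f / (1.0 - f)
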