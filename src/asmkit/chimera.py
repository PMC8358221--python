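"""Chimeric-contig detection and splitting from gene-anchor collinearity.

A chimeric contig erroneously joins segments from different chromosomes.
Given a table assigning each gene on a contig to a reference chromosome
(the output of a collinearity/synteny pipeline), a contig is called
chimeric when it carries a run of at least ``min_run`` consecutive
assigned genes on a single chromosome other than the contig's majority
chromosome (the default of 5 encodes "more than four"). Called contigs
are split midway between the bounding genes of adjacent chromosome
segments.

Unassigned genes carry no evidence either way and by default are skipped
rather than breaking runs; ``strict_unassigned=True`` makes them
run-breaking.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .readops import Read, ReadSet

__all__ = ["ChimeraRun", "ChimeraCall", "detect_chimeras", "split_contigs"]

ANCHOR_COLUMNS = ["contig", "gene_index", "position", "chromosome"]


class ChimeraRun(NamedTuple):
    chromosome: str
    first_gene_index: int
    last_gene_index: int
    run_length: int


@dataclass
class ChimeraCall:
    contig: str
    majority_chromosome: str
    runs: list[ChimeraRun]
    split_positions: list[int]  # base coordinates, strictly inside the contig


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANCHOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"anchor table missing columns: {missing}")
    for contig, grp in table.groupby("contig", sort=False):
        gi = grp["gene_index"].to_numpy()
        order = np.argsort(gi, kind="stable")
        if (np.diff(gi[order]) <= 0).any():
            raise ValueError(f"gene_index not strictly increasing on {contig!r}")
        if (np.diff(grp["position"].to_numpy()[order]) < 0).any():
            raise ValueError(f"positions decrease with gene order on {contig!r}")
    return table


def _is_assigned(v) -> bool:
    return not (pd.isna(v) or v in (".", "", "NA"))


def detect_chimeras(
    table: pd.DataFrame,
    min_run: int = 5,
    strict_unassigned: bool = False,
) -> list[ChimeraCall]:
    """Call chimeric contigs by the run-length rule.

    Per contig: the majority chromosome is the plurality label of its
    assigned genes (ties broken toward the first-encountered label, with a
    warning); maximal runs of consecutive assigned genes on any *other*
    single chromosome of length >= ``min_run`` are reported, each with split
    positions at the midpoint between the bounding genes of adjacent
    segments. Contigs with zero assigned genes are skipped with a warning.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    _validate(table)
    calls: list[ChimeraCall] = []
    for contig, grp in table.groupby("contig", sort=False):
        grp = grp.sort_values("gene_index")
        assigned = grp[[_is_assigned(v) for v in grp["chromosome"]]]
        if assigned.empty:
            warnings.warn(f"contig {contig!r} has no assigned genes; skipped")
            continue
        labels = assigned["chromosome"].tolist()
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab in counts if counts[lab] == best]
        majority = next(lab for lab in labels if lab in winners)
        if len(winners) > 1:
            warnings.warn(
                f"contig {contig!r}: majority-chromosome tie {sorted(winners)}; "
                f"using first-encountered {majority!r}"
            )
        # segment the assigned genes into maximal same-chromosome runs
        gi = assigned["gene_index"].to_numpy()
        pos = assigned["position"].to_numpy()
        if strict_unassigned:
            # consecutive in the full gene order, nothing skipped in between
            full = grp["gene_index"].to_numpy()
            rank = np.searchsorted(full, gi)
            adjacent = np.diff(rank) == 1
        else:
            adjacent = np.ones(len(gi) - 1, dtype=bool)
        segments: list[tuple[str, int, int]] = []  # (chrom, start_idx, end_idx) in assigned order
        start = 0
        for i in range(1, len(labels)):
            if labels[i] != labels[i - 1] or not adjacent[i - 1]:
                segments.append((labels[start], start, i - 1))
                start = i
        segments.append((labels[start], start, len(labels) - 1))
        runs = []
        split_positions: list[int] = []
        for si, (chrom, a, b) in enumerate(segments):
            length = b - a + 1
            if chrom == majority or length < min_run:
                continue
            runs.append(
                ChimeraRun(
                    chromosome=chrom,
                    first_gene_index=int(gi[a]),
                    last_gene_index=int(gi[b]),
                    run_length=length,
                )
            )
            if a > 0:
                split_positions.append(int((pos[a - 1] + pos[a]) // 2))
            if b < len(labels) - 1:
                split_positions.append(int((pos[b] + pos[b + 1]) // 2))
        if runs:
            calls.append(
                ChimeraCall(
                    contig=str(contig),
                    majority_chromosome=majority,
                    runs=runs,
                    split_positions=sorted(set(split_positions)),
                )
            )
    return calls


def split_contigs(
    contigs: ReadSet, calls: Sequence[ChimeraCall]
) -> tuple[ReadSet, pd.DataFrame]:
    """Cut called contigs at their split positions.

    Returns the new contig set (called contigs replaced by suffixed
    fragments, everything else untouched) and an AGP-like provenance table
    with columns (fragment, source, start, end). Total bases are conserved
    exactly; out-of-bounds split positions are an error naming the call.
    """
    by_contig = {c.contig: c for c in calls}
    out: list[Read] = []
    prov = []
    for r in contigs:
        call = by_contig.get(r.id)
        if call is None:
            out.append(r)
            prov.append((r.id, r.id, 0, r.length))
            continue
        cuts = sorted(set(call.split_positions))
        if any(not 0 < p < r.length for p in cuts):
            raise ValueError(
                f"split position out of bounds for contig {r.id!r} "
                f"(length {r.length}): {cuts}"
            )
        bounds = [0] + cuts + [r.length]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            fid = f"{r.id}_part{i + 1}"
            q = None if r.qualities is None else r.qualities[a:b]
            out.append(Read(fid, r.sequence[a:b], q))
            prov.append((fid, r.id, a, b))
    return (
        ReadSet(out, metadata=contigs.metadata),
        pd.DataFrame(prov, columns=["fragment", "source", "start", "end"]),
    )
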