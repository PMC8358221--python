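"""End-to-end pipeline: filter -> stats -> genome size -> assemble/evaluate
-> titrate -> chimera, with a single seed fanned out deterministically to
per-stage seeds and one aggregated JSON report.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from . import asmstats, chimera, io, kmerlab, readops, titration

logger = logging.getLogger("asmkit")

__all__ = ["RunConfig", "PipelineError", "pipeline_run", "stage_seed"]


@dataclass
class RunConfig:
    """Configuration of a full run; thresholds mirror each stage's defaults."""

    reads: str
    outdir: str
    seed: int = 0
    k: int = 21
    min_len: int = 2000
    min_q: float = 7.0
    min_overlap: int = 100
    min_run: int = 5
    min_peak_fraction: float = 0.05
    genome_size: Optional[int] = None  # estimated from k-mers when None
    coverages: Optional[Sequence[float]] = None  # titration disabled when None
    anchors: Optional[str] = None  # chimera stage disabled when None
    assemble: bool = True

    def validate(self):
        if self.min_len < 0 or self.min_q < 0:
            raise ValueError("min_len and min_q must be >= 0")
        if self.min_overlap < 20:
            raise ValueError("min_overlap must be >= 20")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0 < self.min_peak_fraction < 1:
            raise ValueError("min_peak_fraction must be in (0, 1)")
        if not Path(self.reads).exists():
            raise FileNotFoundError(f"reads file not found: {self.reads}")
        if self.anchors is not None and not Path(self.anchors).exists():
            raise FileNotFoundError(f"anchor table not found: {self.anchors}")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return (seed + zlib.crc32(stage.encode())) % (2**31 - 1)


def pipeline_run(config: RunConfig) -> dict:
    """Run every configured stage, writing per-stage outputs under
    ``config.outdir`` and returning the aggregated report (also written as
    ``report.json``). Stage outputs already on disk survive a later failure.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {"asmkit": __version__, "config": {k: (list(v) if isinstance(v, (tuple,)) else v) for k, v in asdict(config).items()}},
        "stages": [],
    }

    def run_stage(name, fn):
        logger.info("stage %s", name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            report["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            io.write_json(report, outdir / "report.json")
            raise PipelineError(name, exc) from exc
        report["stages"].append({"name": name, "status": "ok"})
        return result

    reads = run_stage("load", lambda: io.read_sequences(config.reads))

    def do_filter():
        kept = readops.filter_reads(reads, min_len=config.min_len, min_q=config.min_q)
        io.write_fasta(kept, outdir / "filtered.fasta")
        report["filter"] = {"input_reads": len(reads), "kept_reads": len(kept)}
        return kept

    filtered = run_stage("filter", do_filter)

    def do_stats():
        st = readops.length_stats(filtered)
        report["read_stats"] = {
            "n_reads": st.n_reads,
            "total_bases": st.total_bases,
            "mean": st.mean,
            "n50": st.n50,
            "n90": st.n90,
        }
        return st

    run_stage("read_stats", do_stats)

    def do_gsize():
        table = kmerlab.count_kmers(filtered, k=config.k)
        hist = kmerlab.histogram(table)
        thr = kmerlab.noise_threshold(hist)
        est = kmerlab.estimate_genome_size(hist, thr)
        report["genome_size"] = {
            "k": config.k,
            "noise_threshold": thr.multiplicity,
            "estimate": est.size,
            "peak_depth": est.peak_depth,
            "model": "haploid",
        }
        return table, est

    read_table, gsize = run_stage("genome_size", do_gsize)
    genome_size = config.genome_size or int(round(gsize.size))

    contigs = None
    if config.assemble:

        def do_assemble():
            ctg = titration.greedy_assemble(filtered, min_overlap=config.min_overlap)
            io.write_fasta(ctg, outdir / "contigs.fasta")
            st = asmstats.contig_stats(ctg)
            asm_table = kmerlab.count_kmers(ctg, k=config.k)
            comp = kmerlab.completeness(
                read_table, asm_table, kmerlab.noise_threshold(kmerlab.histogram(read_table))
            )
            report["assembly"] = {
                "n_contigs": st.n_sequences,
                "total": st.total,
                "n50": st.n50,
                "n90": st.n90,
                "completeness": comp,
                "genome_fraction_pct": asmstats.genome_fraction(st.total, genome_size),
            }
            return ctg

        contigs = run_stage("assemble", do_assemble)

    if config.coverages:

        def do_titrate():
            table = titration.run_titration(
                filtered,
                genome_size,
                sorted(config.coverages),
                seed=stage_seed(config.seed, "titration"),
                min_overlap=config.min_overlap,
            )
            table.rows.to_csv(outdir / "titration.tsv", sep="\t", index=False)
            fit = titration.fit_saturation(table)
            report["titration"] = {
                "rows": table.rows.to_dict(orient="records"),
                "fit": {"n_max": fit.n_max, "tau": fit.tau, "rss": fit.rss},
                "coverage_at_80pct": titration.coverage_at_fraction(fit, 0.8),
            }

        run_stage("titration", do_titrate)

    if config.anchors and contigs is not None:

        def do_chimera():
            anchors = io.read_anchor_table(config.anchors)
            calls = chimera.detect_chimeras(anchors, min_run=config.min_run)
            split, prov = chimera.split_contigs(contigs, calls)
            io.write_fasta(split, outdir / "contigs.split.fasta")
            prov.to_csv(outdir / "contigs.split.agp.tsv", sep="\t", index=False)
            report["chimera"] = {
                "n_calls": len(calls),
                "called_contigs": [c.contig for c in calls],
            }

        run_stage("chimera", do_chimera)

    io.write_json(report, outdir / "report.json")
    return report
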