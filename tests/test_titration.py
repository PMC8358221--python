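"""Toy greedy assembler, titration/cut experiments, saturation fitting."""
import math

import numpy as np
import pytest

from asmkit import synthgen as sg
from asmkit.asmstats import contig_stats
from asmkit.readops import CutSpec, Read, ReadSet
from asmkit.titration import (
    SaturationFit,
    coverage_at_fraction,
    fit_saturation,
    greedy_assemble,
    run_cut_series,
    run_titration,
)


def tiling_reads(genome: str, read_len: int, step: int) -> ReadSet:
    recs = []
    i = 0
    for s in range(0, len(genome) - read_len + 1, step):
        recs.append(Read(f"t{i:05d}", genome[s : s + read_len]))
        i += 1
    if (len(genome) - read_len) % step:
        recs.append(Read(f"t{i:05d}", genome[-read_len:]))
    return ReadSet(recs)


class TestGreedyAssemble:
    def test_perfect_tiling_reconstructs_repeat_free_genome(self, small_genome):
        g = small_genome[:10_000]
        reads = tiling_reads(g, read_len=1000, step=500)
        ctg = greedy_assemble(reads, min_overlap=100)
        assert len(ctg) == 1
        assert ctg[0].sequence == g

    def test_repeat_breaks_short_read_assembly(self):
        spec = sg.GenomeSpec(length=30_000, repeat_families=((2000, 2, 0.0),), seed=3)
        g = sg.simulate_genome(spec)
        reads = tiling_reads(g, read_len=1000, step=300)
        ctg = greedy_assemble(reads, min_overlap=100)
        assert len(ctg) >= 3
        for c in ctg:
            assert c.sequence in g  # breaks, but never misjoins

    def test_repeat_spanning_reads_reconstruct(self):
        spec = sg.GenomeSpec(length=30_000, repeat_families=((2000, 2, 0.0),), seed=3)
        g = sg.simulate_genome(spec)
        reads = tiling_reads(g, read_len=5000, step=1000)
        ctg = greedy_assemble(reads, min_overlap=100)
        assert len(ctg) == 1
        assert ctg[0].sequence == g

    def test_simulated_reads_exact_substrings(self, repeat_genome):
        model = sg.fit_length_model(6000, 9000, min_length=1000)
        rs = sg.simulate_reads(repeat_genome, model, coverage=12, seed=4)
        ctg = greedy_assemble(rs, min_overlap=100)
        for c in ctg:
            assert c.sequence in repeat_genome

    def test_refuses_errorful_reads(self, small_genome):
        model = sg.fit_length_model(4000, 5000, min_length=1000)
        rs = sg.simulate_reads(small_genome, model, coverage=5, error_rate=0.01, seed=5)
        with pytest.raises(ValueError, match="error-free"):
            greedy_assemble(rs)

    def test_empty_and_min_overlap_validation(self):
        with pytest.raises(ValueError):
            greedy_assemble(ReadSet([]))
        with pytest.raises(ValueError):
            greedy_assemble(ReadSet([Read("a", "ACGT" * 100)]), min_overlap=10)

    def test_deterministic(self, repeat_genome):
        model = sg.fit_length_model(6000, 9000, min_length=1000)
        rs = sg.simulate_reads(repeat_genome, model, coverage=8, seed=6)
        a = greedy_assemble(rs, min_overlap=100)
        b = greedy_assemble(rs, min_overlap=100)
        assert [c.sequence for c in a] == [c.sequence for c in b]


class TestRunTitration:
    def test_monotone_total_and_determinism(self, small_genome):
        model = sg.fit_length_model(6000, 9000, min_length=1000)
        rs = sg.simulate_reads(small_genome, model, coverage=25, seed=7)
        t1 = run_titration(rs, len(small_genome), [5, 10, 20], seed=1)
        t2 = run_titration(rs, len(small_genome), [5, 10, 20], seed=1)
        assert t1.rows.equals(t2.rows)
        totals = t1.rows["total"].to_numpy()
        # assembled size roughly constant once coverage is adequate
        assert totals[-1] == pytest.approx(len(small_genome), rel=0.1)
        # contiguity improves (or at least does not degrade) with coverage
        n50s = t1.rows["n50"].to_numpy()
        assert n50s[-1] >= n50s[0]

    def test_single_full_coverage_matches_direct_assembly(self, small_genome):
        g = small_genome[:50_000]
        reads = tiling_reads(g, read_len=2000, step=700)
        cov = reads.total_bases / len(g)
        t = run_titration(reads, len(g), [cov], seed=0)
        direct = contig_stats(greedy_assemble(reads, min_overlap=100))
        assert int(t.rows["n50"].iloc[0]) == direct.n50
        assert int(t.rows["n_contigs"].iloc[0]) == direct.n_sequences

    def test_non_increasing_coverages_rejected(self, small_genome):
        rs = tiling_reads(small_genome[:20_000], 1000, 500)
        with pytest.raises(ValueError, match="strictly increasing"):
            run_titration(rs, 20_000, [10, 10], seed=0)

    def test_excess_coverage_propagates_with_step(self, small_genome):
        rs = tiling_reads(small_genome[:20_000], 1000, 500)
        with pytest.raises(RuntimeError, match="coverage 100"):
            run_titration(rs, 20_000, [100], seed=0)


class TestRunCutSeries:
    def test_conservation_and_baseline_dominance(self, repeat_genome):
        model = sg.fit_length_model(9000, 14_000, min_length=1000)
        rs = sg.simulate_reads(repeat_genome, model, coverage=12, seed=8)
        df = run_cut_series(rs, [CutSpec((3000,))])
        assert (df["input_bases"] == rs.total_bases).all()
        base = df[df.label == "uncut"].iloc[0]
        cut = df[df.label == "C3"].iloc[0]
        assert base["n50"] >= cut["n50"]

    def test_spec_larger_than_every_read_is_baseline(self, small_genome):
        g = small_genome[:30_000]
        reads = tiling_reads(g, read_len=2000, step=800)
        df = run_cut_series(reads, [CutSpec((50_000,))])
        assert df["n50"].nunique() == 1 and df["n_contigs"].nunique() == 1

    def test_empty_specs_rejected(self, small_genome):
        with pytest.raises(ValueError):
            run_cut_series(tiling_reads(small_genome[:10_000], 1000, 500), [])


class TestSaturationFit:
    def _exact_points(self, n_max=22.7e6, tau=32.3):
        c = np.arange(10, 91, 10, dtype=float)
        return c, n_max * (1 - np.exp(-c / tau))

    def test_noiseless_recovery_to_1e6(self):
        c, y = self._exact_points()
        fit = fit_saturation((c, y))
        assert fit.n_max == pytest.approx(22.7e6, rel=1e-6)
        assert fit.tau == pytest.approx(32.3, rel=1e-6)
        assert fit.rss < 1.0

    def test_constant_n50_limit(self):
        c = np.array([10.0, 30.0, 60.0, 90.0])
        y = np.full_like(c, 5e6)
        fit = fit_saturation((c, y))
        assert fit.n_max == pytest.approx(5e6, rel=0.01)
        assert fit.tau < c.min()

    def test_noisy_monte_carlo_recovery(self):
        # 5% multiplicative noise, 9 points, 50 seeds: median n_max within 10%
        c, y = self._exact_points()
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fit = fit_saturation((c, y * (1 + 0.05 * rng.standard_normal(c.size))))
            errs.append(fit.n_max / 22.7e6 - 1)
        assert abs(np.median(errs)) < 0.10

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_saturation(([1, 2], [3, 4]))

    def test_michaelis_menten_alternative(self):
        c = np.arange(10, 91, 10, dtype=float)
        y = 20e6 * c / (40 + c)
        fit = fit_saturation((c, y), model="mm")
        assert fit.n_max == pytest.approx(20e6, rel=1e-6)
        assert fit.tau == pytest.approx(40, rel=1e-6)


class TestCoverageAtFraction:
    def test_80pct_anchor(self):
        fit = SaturationFit(n_max=22.7e6, tau=32.3, rss=0, n_points=9)
        assert coverage_at_fraction(fit, 0.8) == pytest.approx(52.0, abs=0.05)

    def test_90pct_exponential_prediction(self):
        fit = SaturationFit(n_max=22.7e6, tau=32.3, rss=0, n_points=9)
        assert coverage_at_fraction(fit, 0.9) == pytest.approx(74.4, abs=0.05)

    def test_round_trip_with_fit(self):
        c = np.arange(10, 91, 10, dtype=float)
        y = 22.7e6 * (1 - np.exp(-c / 32.3))
        fit = fit_saturation((c, y))
        for f in (0.25, 0.5, 0.8, 0.95):
            cf = coverage_at_fraction(fit, f)
            assert fit.predict(cf) == pytest.approx(f * fit.n_max, rel=1e-6)

    def test_fraction_bounds(self):
        fit = SaturationFit(n_max=1, tau=1, rss=0, n_points=3)
        for f in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                coverage_at_fraction(fit, f)


class TestReadLengthDominance:
    def test_longer_reads_give_larger_n50_on_repeat_genome(self, repeat_genome):
        # two length regimes straddling the 8 kb repeat unit
        short_model = sg.fit_length_model(3000, 4500, min_length=1000)
        long_model = sg.fit_length_model(15_000, 22_000, min_length=1000)
        n50s = []
        for model in (short_model, long_model):
            vals = []
            for seed in range(3):
                rs = sg.simulate_reads(repeat_genome, model, coverage=12, seed=100 + seed)
                vals.append(contig_stats(greedy_assemble(rs, min_overlap=100)).n50)
            n50s.append(np.mean(vals))
        assert n50s[1] > n50s[0]
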