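"""k-mer genome-size estimation and assembly completeness.

Counts canonical 21-mers in simulated short reads, locates the noise
threshold and coverage peak of the multiplicity histogram, estimates the
genome size, and measures completeness of a deliberately truncated
assembly by read/assembly k-mer intersection.
"""
from asmkit import synthgen as sg
from asmkit.kmerlab import (
    completeness,
    count_kmers,
    estimate_genome_size,
    histogram,
    noise_threshold,
)

GENOME_LEN = 300_000
genome = sg.simulate_genome(sg.GenomeSpec(length=GENOME_LEN, seed=5))
reads = sg.simulate_reads(genome, sg.fit_length_model(150, 150), coverage=40, seed=6)

table = count_kmers(reads, k=21)
hist = histogram(table)
thr = noise_threshold(hist)
est = estimate_genome_size(hist, thr)
print(f"distinct 21-mers: {table.n_distinct}  noise threshold: {thr.multiplicity}")
print(f"estimated genome size: {est.size / 1e3:.1f} kb (truth {GENOME_LEN / 1e3:.0f} kb)")
print(f"k-mer coverage peak: {est.peak_depth:.1f}x")
# the estimate is solid k-mer instances divided by the coverage peak; with
# error-free reads the noise threshold sits at the bottom of the histogram.

full = count_kmers(genome, k=21)
partial = count_kmers(genome[: int(0.9 * len(genome))], k=21)
print(f"\ncompleteness, full assembly:      {100 * completeness(table, full, thr):.2f}%")
print(f"completeness, 10% deleted:        {100 * completeness(table, partial, thr):.2f}%")
# deleting a tenth of a repeat-free genome removes ~10% of its distinct
# k-mers, and the completeness statistic reports just that.
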