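import numpy as np
import pytest

from asmkit import synthgen as sg
from asmkit.readops import Read, ReadSet


@pytest.fixture(scope="session")
def small_genome() -> str:
    """200 kb repeat-free genome used across modules."""
    return sg.simulate_genome(sg.GenomeSpec(length=200_000, seed=11))


@pytest.fixture(scope="session")
def repeat_genome() -> str:
    """200 kb genome with six exact 8 kb repeat copies (breaks short-read paths)."""
    spec = sg.GenomeSpec(length=200_000, repeat_families=((8000, 6, 0.0),), seed=7)
    return sg.simulate_genome(spec)


@pytest.fixture
def quality_reads() -> ReadSet:
    """Hand-built reads with known lengths and constant qualities."""
    return ReadSet(
        [
            Read("a", "ACGT" * 375, np.full(1500, 12, dtype=np.uint8)),  # 1.5 kb Q12
            Read("b", "ACGT" * 500, np.full(2000, 7, dtype=np.uint8)),  # 2.0 kb Q7
            Read("c", "ACGT" * 625, np.full(2500, 5, dtype=np.uint8)),  # 2.5 kb Q5
            Read("d", "ACGT" * 750, None),  # 3.0 kb, no qualities
        ]
    )


def brute_force_nx(lengths, x):
    """Independent O(n^2)-ish oracle for Nx/Lx from the definition."""
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    running = 0
    for i, L in enumerate(srt):
        running += L
        if running >= x / 100.0 * total:
            return L, i + 1
    raise AssertionError("unreachable for x <= 100")
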