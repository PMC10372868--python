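"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dpcoa_tagseq.read_sim import DEFAULT_TAG_SEQUENCE
from dpcoa_tagseq.tag_classify import TagSpec


@pytest.fixture(scope="session")
def tag_spec() -> TagSpec:
    """The default 40-nt tag with the k=12 / window=50 rule."""
    return TagSpec(DEFAULT_TAG_SEQUENCE, k=12, window=50)


def brute_force_match(seq: str, tag: str, k: int, window: int):
    """Exhaustive seed search over every (read position, tag offset) pair.

    Independent oracle for the classifier: returns the leftmost read
    position (smallest tag offset at that position) of an exact k-mer
    shared between the first ``window`` bases of the read and the tag,
    or None.  Deliberately naive: no index, no early exit beyond the
    leftmost-first ordering.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) < k:
        return None
    for i in range(min(len(seq), window) - k + 1):
        for j in range(len(tag) - k + 1):
            if seq[i : i + k] == tag[j : j + k]:
                return i, j
    return None


def brute_force_extension(seq: str, tag: str, k: int, i: int, j: int) -> int:
    """Replay the greedy rightward extension from a seed; returns match_end."""
    e, t = i + k, j + k
    while e < len(seq) and t < len(tag) and seq[e] == tag[t] and seq[e] != "N":
        e += 1
        t += 1
    return e


def random_reads(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Uniform A/C/G/T reads."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        bases[rng.integers(0, 4, size=length)].tobytes().decode() for _ in range(n)
    ]


def welch_reference(x, y) -> float:
    """Hand-coded Welch t-test (Welch-Satterthwaite df), independent of scipy.

    Oracle for the package's welch_t_test: computes the t statistic
    and two-sided p from first principles, using only the incomplete
    beta function through scipy.special (not scipy.stats.ttest_ind).
    """
    from scipy.special import betainc

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    sx, sy = vx / nx, vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
    # two-sided p via the t-distribution survival function:
    # P(|T| > t) = I_{df/(df+t^2)}(df/2, 1/2)
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))
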