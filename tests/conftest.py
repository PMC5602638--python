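"""Shared fixtures and independent oracle implementations.

The oracles deliberately use the most literal, brute-force formulation
of each rule so they stay independent of the optimized implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from valleytf.coverage import CoverageTrack, ValleyParams
from valleytf.motifscan import PWM


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_track(values, chrom="chr1", origin=0, step=10) -> CoverageTrack:
    return CoverageTrack(chrom, origin, step, np.asarray(values, dtype=float))


# ---------------------------------------------------------------- oracles


def valley_calls_oracle(track: CoverageTrack, params: ValleyParams):
    """Literal per-point application of the valley rule, then run merging.

    For each sample point, scan both flanking windows exhaustively; the
    point is a valley iff its value is strictly below dip_fraction times
    the minimum of the two window maxima, scored by that minimum.
    """
    step = track.step
    nb, fb = params.near // step, params.far // step
    vals = track.values
    n = len(vals)
    point_scores = np.zeros(n)
    for i in range(n):
        left = vals[max(0, i - fb) : i - nb + 1] if i - nb >= 0 else vals[0:0]
        right = vals[i + nb : min(n - 1, i + fb) + 1]
        if len(left) == 0 or len(right) == 0:
            continue
        m = min(left.max(), right.max())
        if vals[i] < params.dip_fraction * m:
            point_scores[i] = m
    calls = []
    i = 0
    while i < n:
        if point_scores[i] > 0:
            j = i
            while j < n and point_scores[j] > 0:
                j += 1
            calls.append(
                (
                    track.origin + step * i,
                    track.origin + step * j,
                    float(point_scores[i:j].max()),
                )
            )
            i = j
        else:
            i += 1
    return calls


def coverage_oracle_at(reads, pos: int) -> int:
    """Brute-force per-bp coverage: number of reads whose interval contains pos."""
    return int(sum(1 for _, row in reads.iterrows() if row["start"] <= pos < row["end"]))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def alr_oracle(pwm: PWM, seq: str, bg_freqs) -> float:
    """Exhaustive placement enumeration of the average likelihood ratio.

    Walks every placement on both strands, multiplying per-base
    probability ratios directly (N contributes a neutral factor 1); the
    reverse strand scores the reverse complement of the window against
    the PWM and the background.
    """
    bg = {b: f for b, f in zip("ACGT", bg_freqs)}
    seq = seq.upper()
    w = pwm.width
    total = 0.0
    n_place = len(seq) - w + 1
    assert n_place >= 1
    for i in range(n_place):
        window = seq[i : i + w]
        for sub in (window, revcomp(window)):
            lr = 1.0
            for j, b in enumerate(sub):
                if b not in "ACGT":
                    continue
                lr *= pwm.probs[j, "ACGT".index(b)] / bg[b]
            total += lr
    return total / (2 * n_place)


def bh_oracle(p):
    """Independent BH step-up: sort, scale by m/rank, cummin from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation, term by term."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = x.sum() / n, y.sum() / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = (
        sum((xi - mx) ** 2 for xi in x) ** 0.5
        * sum((yi - my) ** 2 for yi in y) ** 0.5
    )
    return num / den
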