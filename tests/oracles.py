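"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: entropy and
compositional probabilities are computed with ``collections.Counter``,
``math.factorial`` and exact ``fractions.Fraction`` arithmetic, and every
subsequence is enumerated outright.
"""

from __future__ import annotations

import math
from collections import Counter
from fractions import Fraction

import numpy as np


def shannon_bits(window: str) -> float:
    counts = Counter(window)
    L = len(window)
    return -sum((c / L) * math.log2(c / L) for c in counts.values())


def exact_p0(subseq: str) -> Fraction:
    """Compositional probability Omega * F / 20^L with exact integers."""
    L = len(subseq)
    counts = Counter(subseq)
    omega = math.factorial(L)
    for c in counts.values():
        omega //= math.factorial(c)
    multiplicity = Counter(counts.values())
    multiplicity[0] = 20 - len(counts)
    f = math.factorial(20)
    for r in multiplicity.values():
        f //= math.factorial(r)
    return Fraction(omega * f, 20**L)


def brute_force_seg(
    seq: str, W: int = 12, k_low: float = 2.2, k_high: float = 2.5
) -> list[tuple[int, int]]:
    """Exhaustive two-stage low-complexity scan; returns (start, end) pairs.

    Stage 1 scans every window directly; stage 2 scores every subsequence of
    each candidate region with exact rational P0 (ties: longest then
    leftmost, i.e. minimal start).
    """
    L = len(seq)
    if L < W:
        return []
    ent = [shannon_bits(seq[i : i + W]) for i in range(L - W + 1)]
    low = [e <= k_low for e in ent]
    high = [e <= k_high for e in ent]

    spans = []
    i = 0
    while i < len(ent):
        if not high[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(ent) and high[j + 1]:
            j += 1
        if any(low[i : j + 1]):
            spans.append((i, j + W))
        i = j + 1
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    out = []
    for s, e in merged:
        best = None
        for a in range(s, e):
            for b in range(a + 1, e + 1):
                key = (exact_p0(seq[a:b]), -(b - a), a)
                if best is None or key < best[0]:
                    best = (key, (a, b))
        out.append(best[1])
    return out


def circular_error_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute angular difference in degrees, wrapped to [0, 180]."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return np.abs((d + 180.0) % 360.0 - 180.0)


def random_biased_sequence(rng: np.random.Generator, max_len: int = 40) -> str:
    """Random test sequence with a per-sequence compositional bias."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    length = int(rng.integers(5, max_len + 1))
    dominant = alphabet[rng.integers(20)]
    p_dom = rng.uniform(0.2, 0.9)
    out = []
    for _ in range(length):
        if rng.random() < p_dom:
            out.append(dominant)
        else:
            out.append(alphabet[rng.integers(20)])
    return "".join(out)
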