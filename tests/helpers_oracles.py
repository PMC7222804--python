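"""Independent brute-force oracles used by the property tests.

These recompute detector output by direct definition — per-base window
checks with plain string slicing for the island caller, exhaustive segment
enumeration for the running-sum seeker — sharing no code with the
vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np

from mtcpg.islands import ScanParams
from mtcpg.cpgseek import SeekParams


def brute_islands(seq: str, p: ScanParams) -> list[tuple[int, int]]:
    """Island intervals (1-based inclusive) by direct per-base evaluation."""
    L = len(seq)
    flags = [False] * L
    for s in range(0, L - p.window + 1, p.shift):
        win = seq[s:s + p.window]
        nc, ng = win.count("C"), win.count("G")
        ncg = win.count("CG")
        pct = 100.0 * (nc + ng) / p.window
        oe = ncg * p.window / (nc * ng) if nc and ng else 0.0
        if oe >= p.min_obs_exp and pct >= p.min_pct_cg:
            if p.attribution == "midpoint":
                lo = s + p.window // 2
                hi = min(lo + p.shift, L)
            else:  # cover
                lo, hi = s, s + p.window
            for q in range(lo, hi):
                flags[q] = True
    out = []
    i = 0
    while i < L:
        if flags[i]:
            j = i
            while j + 1 < L and flags[j + 1]:
                j += 1
            if j - i + 1 >= p.min_length:
                out.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return out


def _scores(seq: str, p: SeekParams) -> np.ndarray:
    return np.array([p.cpg_score if seq[k:k + 2] == "CG" else -p.gap_penalty
                     for k in range(len(seq) - 1)], dtype=np.int64)


def _enumerate_best(scores: np.ndarray, lo: int, hi: int):
    """Best segment of scores[lo:hi] by exhaustive enumeration.

    Ties: leftmost start, then shortest.  Returns (sum, i, j) or None.
    """
    best = None
    for i in range(lo, hi):
        sums = np.cumsum(scores[i:hi])
        j_rel = int(np.argmax(sums))  # first argmax -> shortest for this i
        tot = int(sums[j_rel])
        if best is None or tot > best[0]:
            best = (tot, i, i + j_rel)
    return best


def brute_seek(seq: str, p: SeekParams) -> list[tuple[int, int, int]]:
    """(start, end, score) of reported regions, 1-based inclusive intervals."""
    scores = _scores(seq, p)
    found: list[tuple[int, int, int]] = []

    def rec(lo: int, hi: int) -> None:
        if hi - lo < 1:
            return
        best = _enumerate_best(scores, lo, hi)
        tot, i, j = best
        ok = tot > p.threshold if p.strict else tot >= p.threshold
        if not ok:
            return
        found.append((i + 1, j + 2, tot))
        rec(lo, i)
        rec(j + 1, hi)

    rec(0, len(scores))
    return sorted(found)


def random_genome(rng: np.random.Generator, length: int) -> str:
    """Random test genome: depleted background with occasional CpG-rich
    patches so detectors have something to find."""
    from mtcpg.synthetic import transition_matrix, stationary_pi, _sample_chain

    parts = []
    remaining = length
    while remaining > 0:
        n = int(min(remaining, rng.integers(80, 400)))
        if rng.random() < 0.35:
            gc = float(rng.uniform(0.50, 0.70))
            oe = float(rng.uniform(0.8, 1.8))
        else:
            gc = float(rng.uniform(0.25, 0.50))
            oe = float(rng.uniform(0.05, 0.6))
        T = transition_matrix(gc, oe)
        parts.append(_sample_chain(n, T, stationary_pi(gc),
                                   np.random.default_rng(rng.integers(2**31))))
        remaining -= n
    return "".join(parts)
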