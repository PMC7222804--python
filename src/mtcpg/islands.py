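"""Sliding-window CpG island caller.

A window of fixed width slides along the sequence; in each window the
%C+%G and the observed/expected CpG ratio

    obs/exp = N_CpG * N / (N_C * N_G)

are computed.  The window's values are attributed to its midpoint base (the
rule the classic EMBOSS plotter uses), a base passes when both thresholds
are met, and maximal runs of passing bases at least ``min_length`` long are
reported as islands.  Island-level statistics are then recomputed over the
island subsequence, which is what the report columns show.

Because the first and last ``window//2`` bases of a linear sequence receive
no window value, island calls near the sequence ends differ between the two
strands — the main source of L/H asymmetry in strand-aware scans.  The
alternative ``cover`` attribution (every base of a passing window is
flagged) is available for differential comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .seqio import FeatureTable, GenomeRecord, Interval, map_interval_to_reference

Attribution = Literal["midpoint", "cover"]


@dataclass(frozen=True)
class ScanParams:
    """Island-calling parameters (defaults are the classic criteria:
    obs/exp >= 0.6, %C+%G >= 50 over >= 200 bp, window 100, shift 1)."""

    window: int = 100
    shift: int = 1
    min_length: int = 200
    min_obs_exp: float = 0.6
    min_pct_cg: float = 50.0
    attribution: Attribution = "midpoint"
    circular: bool = False

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ParameterError("window must be >= 2")
        if self.shift < 1:
            raise ParameterError("shift must be >= 1")
        if self.min_length < self.window:
            raise ParameterError("min_length must be >= window")


@dataclass(frozen=True)
class WindowStats:
    window_start: int  # 1-based start of the window
    pct_cg: float
    obs_exp: float


@dataclass(frozen=True)
class CpGIsland:
    interval: Interval
    length: int
    cg_sum: int
    pct_cg: float
    obs_exp: float
    strand: str = "L"


def round2(x: float) -> float:
    """Round half-up to 2 decimal places (table formatting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# per-window statistics

def obs_exp_ratio(subseq: str) -> float:
    """Observed/expected CpG ratio of a subsequence; 0 when C or G absent."""
    if not subseq:
        raise ParameterError("empty subsequence")
    s = subseq.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cpg = s.count("CG")  # CG cannot overlap itself
    return n_cpg * len(s) / (n_c * n_g)


def cg_fraction_stats(subseq: str) -> tuple[int, float, float]:
    """(cg_sum, pct_cg, obs_exp) of a subsequence."""
    s = subseq.upper()
    cg_sum = s.count("C") + s.count("G")
    return cg_sum, 100.0 * cg_sum / len(s), obs_exp_ratio(s)


def _indicator_arrays(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = a == ord("C")
    is_g = a == ord("G")
    cpg = is_c[:-1] & is_g[1:] if len(a) > 1 else np.zeros(0, bool)
    return is_c, is_g, cpg


def _window_arrays(seq: str, p: ScanParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """0-based window starts plus per-window pct and obs/exp (vectorised)."""
    L = len(seq)
    w = p.window
    if p.circular:
        seq = seq + seq[: w - 1]
        starts = np.arange(0, L, p.shift)
    else:
        if L < w:
            raise ParameterError(f"sequence ({L} bp) shorter than window ({w} bp)")
        starts = np.arange(0, L - w + 1, p.shift)
    is_c, is_g, cpg = _indicator_arrays(seq)
    pc = np.concatenate(([0], np.cumsum(is_c)))
    pg = np.concatenate(([0], np.cumsum(is_g)))
    pcg = np.concatenate(([0], np.cumsum(cpg)))
    n_c = pc[starts + w] - pc[starts]
    n_g = pg[starts + w] - pg[starts]
    # CpG starts strictly inside the window: positions start .. start+w-2
    n_cpg = pcg[np.minimum(starts + w - 1, len(cpg))] - pcg[starts]
    pct = 100.0 * (n_c + n_g) / w
    denom = (n_c * n_g).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, n_cpg * w / denom, 0.0)
    return starts, pct, oe


def window_profile(g: GenomeRecord, p: ScanParams = ScanParams()) -> list[WindowStats]:
    """Per-window %C+%G and obs/exp along the genome."""
    starts, pct, oe = _window_arrays(g.sequence, p)
    return [WindowStats(int(s) + 1, float(a), float(b))
            for s, a, b in zip(starts, pct, oe)]


# ---------------------------------------------------------------------------
# island calling

def _flags_from_windows(starts: np.ndarray, passing: np.ndarray,
                        L: int, p: ScanParams) -> np.ndarray:
    flags = np.zeros(L, dtype=bool)
    half = p.window // 2
    if p.attribution == "midpoint":
        # a window's verdict lands on its midpoint (and the shift block after
        # it when shift > 1)
        for s in starts[passing]:
            lo = (s + half) % L if p.circular else s + half
            hi = min(lo + p.shift, L)
            flags[lo:hi] = True
            if p.circular and lo + p.shift > L:
                flags[: (lo + p.shift) % L] = True
    elif p.attribution == "cover":
        for s in starts[passing]:
            hi = s + p.window
            if hi <= L:
                flags[s:hi] = True
            else:  # circular wrap
                flags[s:L] = True
                flags[: hi - L] = True
    else:  # pragma: no cover - guarded by ScanParams
        raise ParameterError(f"unknown attribution rule {p.attribution}")
    return flags


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based inclusive (start, end) pairs."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flags.view(np.int8), [0]))))
    return [(int(s), int(e) - 1) for s, e in zip(edges[::2], edges[1::2])]


def call_islands(profile: Sequence[WindowStats], g: GenomeRecord,
                 p: ScanParams = ScanParams()) -> list[CpGIsland]:
    """Call islands from a window profile of ``g`` computed with ``p``."""
    starts = np.array([w.window_start - 1 for w in profile], dtype=int)
    pct = np.array([w.pct_cg for w in profile])
    oe = np.array([w.obs_exp for w in profile])
    passing = (oe >= p.min_obs_exp) & (pct >= p.min_pct_cg)
    flags = _flags_from_windows(starts, passing, g.length, p)
    islands = []
    frame = "reference" if g.strand == "L" else "reversed"
    for s0, e0 in _runs(flags):
        if e0 - s0 + 1 < p.min_length:
            continue
        sub = g.sequence[s0:e0 + 1]
        cg_sum, pct_cg, obs_exp = cg_fraction_stats(sub)
        islands.append(CpGIsland(
            interval=Interval(s0 + 1, e0 + 1, frame=frame),
            length=e0 - s0 + 1, cg_sum=cg_sum, pct_cg=pct_cg,
            obs_exp=obs_exp, strand=g.strand))
    return islands


def find_islands(g: GenomeRecord, p: ScanParams = ScanParams()) -> list[CpGIsland]:
    """Convenience: profile + call in one step."""
    return call_islands(window_profile(g, p), g, p)


# ---------------------------------------------------------------------------
# reporting

def island_report(islands: Sequence[CpGIsland], genome_length: int,
                  features: FeatureTable | None = None) -> pd.DataFrame:
    """One row per island with the comparative-table columns.

    H-strand islands are mapped to reference coordinates so their feature
    labels line up with the annotation.
    """
    rows = []
    for isl in islands:
        iv = isl.interval
        if iv.frame == "reversed":
            iv = map_interval_to_reference(iv, genome_length)
        region = ""
        if features is not None:
            region = ", ".join(f.name for f in features.overlapping(iv))
        rows.append({
            "start": iv.start, "end": iv.end, "region": region,
            "length": isl.length, "cg_sum": isl.cg_sum,
            "pct_cg": round2(isl.pct_cg), "obs_exp": round2(isl.obs_exp),
            "strand": isl.strand,
        })
    cols = ["start", "end", "region", "length", "cg_sum",
            "pct_cg", "obs_exp", "strand"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["strand", "start"], kind="stable").reset_index(drop=True)
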