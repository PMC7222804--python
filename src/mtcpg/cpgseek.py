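"""Running-sum CpG-rich region detector.

Every sequence position that starts a CG dinucleotide contributes a fixed
positive score (default +17); every other position contributes a penalty
(default -1).  Maximal-scoring segments of this score stream whose total
reaches the threshold (default 17) are reported, found by recursive
subdivision: the best segment of the range is taken, then its left and
right flanks are searched in turn.  A maximal segment necessarily begins at
the C of a CG and ends at the G of one, because trimming a penalty position
off either end would raise the score.

Compared with the sliding-window island caller this deliberately
over-predicts: a lone CG already reaches an inclusive threshold of 17,
which is what makes short tRNA-cluster regions visible.  Per-region CpG
counts summed per strand give the strand totals of comparative tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .islands import cg_fraction_stats, round2
from .seqio import FeatureTable, GenomeRecord, Interval, map_interval_to_reference


@dataclass(frozen=True)
class SeekParams:
    """Scoring parameters: +cpg_score per CG start, -gap_penalty elsewhere,
    report segments with score >= threshold (or > with strict=True)."""

    cpg_score: int = 17
    gap_penalty: int = 1
    threshold: int = 17
    strict: bool = False
    circular: bool = False

    def __post_init__(self) -> None:
        if self.cpg_score < 1 or self.gap_penalty < 1 or self.threshold < 1:
            raise ParameterError("cpg_score, gap_penalty, threshold must be >= 1")

    def admits(self, score: int) -> bool:
        return score > self.threshold if self.strict else score >= self.threshold


@dataclass(frozen=True)
class CpGRegion:
    interval: Interval
    score: int
    cpg_count: int
    cg_sum: int
    obs_exp: float
    strand: str = "L"


def _score_stream(seq: str, p: SeekParams) -> np.ndarray:
    """Score per dinucleotide start position (0-based).

    Linear mode has L-1 positions; circular mode appends the wrap-around
    dinucleotide s[L-1]+s[0] as position L-1.
    """
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_cg = (a[:-1] == ord("C")) & (a[1:] == ord("G"))
    if p.circular:
        wrap = np.array([seq[-1] == "C" and seq[0] == "G"])
        is_cg = np.concatenate((is_cg, wrap))
    return np.where(is_cg, p.cpg_score, -p.gap_penalty).astype(np.int64)


def _best_segment(scores: np.ndarray, lo: int, hi: int) -> tuple[int, int, int]:
    """Maximum-sum segment of scores[lo:hi] (0-based, half-open).

    Ties resolve to the leftmost start, then the shortest segment.  Returns
    (sum, start, end_inclusive).
    """
    window = scores[lo:hi]
    prefix = np.concatenate(([0], np.cumsum(window)))
    run_min = np.minimum.accumulate(prefix[:-1])
    cand = prefix[1:] - run_min  # best sum of a segment ending at each j
    j = int(np.argmax(cand))    # first argmax -> leftmost start, shortest
    i = int(np.argmin(prefix[: j + 1]))
    return int(cand[j]), lo + i, lo + j


def _recurse(scores: np.ndarray, lo: int, hi: int, p: SeekParams,
             out: list[tuple[int, int, int]]) -> None:
    if hi - lo < 1:
        return
    s, i, j = _best_segment(scores, lo, hi)
    if not p.admits(s):
        return  # the best segment of the range fails; every sub-segment does too
    out.append((s, i, j))
    _recurse(scores, lo, i, p, out)
    _recurse(scores, j + 1, hi, p, out)


def seek_regions(g: GenomeRecord, p: SeekParams = SeekParams()) -> list[CpGRegion]:
    """All maximal-scoring CpG-rich segments of ``g`` above threshold."""
    if g.length < 2:
        raise ParameterError("sequence must be at least 2 bp")
    scores = _score_stream(g.sequence, p)
    found: list[tuple[int, int, int]] = []
    _recurse(scores, 0, len(scores), p, found)
    frame = "reference" if g.strand == "L" else "reversed"
    regions = []
    for score, i, j in sorted(found, key=lambda t: t[1]):
        # stream position k covers bases k, k+1; segment ends at the G of
        # its last CG
        end0 = j + 1
        if end0 >= g.length:  # circular wrap dinucleotide
            end0 = g.length - 1
        sub = g.sequence[i:end0 + 1]
        cg_sum, _, oe = cg_fraction_stats(sub)
        cpg = sub.count("CG") + (1 if p.circular and end0 == g.length - 1
                                 and j == g.length - 1 else 0)
        regions.append(CpGRegion(
            interval=Interval(i + 1, end0 + 1, frame=frame),
            score=int(score), cpg_count=int(cpg), cg_sum=cg_sum,
            obs_exp=oe, strand=g.strand))
    return regions


def region_sites(regions: Sequence[CpGRegion]) -> int:
    """Total CpG sites across regions (one strand of one genome)."""
    return int(sum(r.cpg_count for r in regions))


def region_report(regions: Sequence[CpGRegion], genome_length: int,
                  features: FeatureTable | None = None) -> pd.DataFrame:
    """One row per region; H-strand rows are mapped to reference coordinates."""
    rows = []
    for r in regions:
        iv = r.interval
        if iv.frame == "reversed":
            iv = map_interval_to_reference(iv, genome_length)
        region = ""
        if features is not None:
            region = ", ".join(f.name for f in features.overlapping(iv))
        length = r.interval.length
        rows.append({
            "start": iv.start, "end": iv.end, "region": region,
            "score": r.score, "cpg_count": r.cpg_count, "cg_sum": r.cg_sum,
            "pct_cg": round2(100.0 * r.cg_sum / length),
            "obs_exp": round2(r.obs_exp), "strand": r.strand,
        })
    cols = ["start", "end", "region", "score", "cpg_count", "cg_sum",
            "pct_cg", "obs_exp", "strand"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["strand", "start"], kind="stable").reset_index(drop=True)
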