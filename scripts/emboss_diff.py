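#!/usr/bin/env python
"""Differential comparison against the original EMBOSS tools.

If ``cpgplot`` and/or ``newcpgseek`` are on PATH, runs them on a FASTA file
and prints their island/region intervals next to ours, so edge-handling and
window-attribution conventions can be reconciled empirically.  The original
tools are not bundled.

Usage:  python scripts/emboss_diff.py genome.fasta [--attribution midpoint|cover]
"""

from __future__ import annotations

import argparse
import re
import shutil
import subprocess
import sys
import tempfile
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mtcpg.cpgseek import SeekParams, seek_regions  # noqa: E402
from mtcpg.islands import ScanParams, find_islands  # noqa: E402
from mtcpg.seqio import read_fasta  # noqa: E402


def run_cpgplot(fasta: Path, tmp: Path) -> list[tuple[int, int]]:
    out = tmp / "cpgplot.out"
    subprocess.run(
        ["cpgplot", "-sequence", str(fasta), "-window", "100", "-minlen",
         "200", "-minoe", "0.6", "-minpc", "50", "-outfile", str(out),
         "-outfeat", str(tmp / "cpgplot.gff"), "-noplot", "-auto"],
        check=True, capture_output=True)
    islands = []
    for m in re.finditer(r"Length (\d+) \((\d+)\.\.(\d+)\)", out.read_text()):
        islands.append((int(m.group(2)), int(m.group(3))))
    return islands


def run_newcpgseek(fasta: Path, tmp: Path) -> list[tuple[int, int, int]]:
    out = tmp / "newcpgseek.out"
    subprocess.run(
        ["newcpgseek", "-sequence", str(fasta), "-score", "17",
         "-outfile", str(out), "-auto"],
        check=True, capture_output=True)
    rows = []
    for line in out.read_text().splitlines():
        m = re.match(r"\s*(\d+)\s+(\d+)\s+(\d+)\s+(\d+)", line)
        if m:
            rows.append((int(m.group(1)), int(m.group(2)), int(m.group(3))))
    return rows


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("fasta", type=Path)
    ap.add_argument("--attribution", choices=["midpoint", "cover"],
                    default="midpoint")
    args = ap.parse_args()

    genome = read_fasta(args.fasta)
    ours_islands = [(i.interval.start, i.interval.end)
                    for i in find_islands(genome,
                                          ScanParams(attribution=args.attribution))]
    ours_regions = [(r.interval.start, r.interval.end, r.score)
                    for r in seek_regions(genome, SeekParams())]
    print(f"mtcpg islands ({args.attribution}): {ours_islands}")
    print(f"mtcpg regions: {len(ours_regions)} "
          f"(first five: {ours_regions[:5]})")

    with tempfile.TemporaryDirectory() as td:
        tmp = Path(td)
        if shutil.which("cpgplot"):
            emboss = run_cpgplot(args.fasta, tmp)
            print(f"cpgplot islands: {emboss}")
            print("island agreement:",
                  "EXACT" if emboss == ours_islands else "DIFFERS")
        else:
            print("cpgplot not on PATH; skipping island comparison")
        if shutil.which("newcpgseek"):
            emboss_r = run_newcpgseek(args.fasta, tmp)
            print(f"newcpgseek regions: {len(emboss_r)} "
                  f"(first five: {emboss_r[:5]})")
        else:
            print("newcpgseek not on PATH; skipping region comparison")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
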