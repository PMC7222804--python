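"""Single-genome and multi-species scan orchestration.

``run_scan`` executes, per input genome and per requested strand, the
island caller and the running-sum seeker, annotates the detections and
writes deterministic TSV outputs (no timestamps, stable ordering).
``run_compare`` merges scan outputs from several species into the
comparative tables: islands per strand, the per-gene CpG-count matrix with
strand totals, and the multi-feature region table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from . import annotate, cpgseek, islands, seqio
from .errors import InputFormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesInput:
    sequence: str              # FASTA path
    label: str
    features: str | None = None
    feature_dialect: str = "tsv"
    group: str = ""            # e.g. vertebrate / invertebrate


@dataclass(frozen=True)
class RunConfig:
    inputs: tuple[SpeciesInput, ...]
    scan: islands.ScanParams = islands.ScanParams()
    seek: cpgseek.SeekParams = cpgseek.SeekParams()
    strands: Literal["L", "H", "both"] = "both"
    outdir: str = "mtcpg-out"
    density_step: int = 10

    def __post_init__(self) -> None:
        if not self.inputs:
            raise InputFormatError("config lists no inputs")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run manifest (see examples/manifest.yaml)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    inputs = tuple(
        SpeciesInput(sequence=i["sequence"], label=i["label"],
                     features=i.get("features"),
                     feature_dialect=i.get("feature_dialect", "tsv"),
                     group=i.get("group", ""))
        for i in doc.get("inputs", []))
    scan = islands.ScanParams(**doc.get("scan", {}))
    seek = cpgseek.SeekParams(**doc.get("seek", {}))
    return RunConfig(inputs=inputs, scan=scan, seek=seek,
                     strands=doc.get("strands", "both"),
                     outdir=doc.get("outdir", "mtcpg-out"),
                     density_step=doc.get("density_step", 10))


def _strand_records(genome: seqio.GenomeRecord,
                    strands: str) -> list[seqio.GenomeRecord]:
    recs = []
    if strands in ("L", "both"):
        recs.append(genome)
    if strands in ("H", "both"):
        recs.append(seqio.reverse_complement(genome))
    return recs


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def scan_one(genome: seqio.GenomeRecord,
             features: seqio.FeatureTable | None,
             scan: islands.ScanParams,
             seek: cpgseek.SeekParams) -> dict:
    """Scan one strand record: islands, regions, annotations, density."""
    profile = islands.window_profile(genome, scan)
    isl = islands.call_islands(profile, genome, scan)
    regions = cpgseek.seek_regions(genome, seek)
    anns = (annotate.classify_regions(regions, features)
            if features is not None else [])
    return {"profile": profile, "islands": isl, "regions": regions,
            "annotations": anns}


def run_scan(config: RunConfig) -> dict[str, dict]:
    """Run the full scan; returns results and writes per-strand TSVs.

    Output files per species X and strand S: ``X.S.islands.tsv``,
    ``X.S.regions.tsv``, ``X.S.annotations.tsv``, ``X.S.density.tsv``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, dict] = {}
    for inp in config.inputs:
        genome = seqio.read_fasta(inp.sequence)
        L = genome.length
        ft = None
        if inp.features:
            ft = seqio.read_features(inp.features, inp.feature_dialect,
                                     genome_length=L)
        logger.info("scanning %s (%d bp), strands=%s, window=%d shift=%d "
                    "min_len=%d min_oe=%.2f min_pct=%.1f score=%d thr=%d",
                    inp.label, L, config.strands, config.scan.window,
                    config.scan.shift, config.scan.min_length,
                    config.scan.min_obs_exp, config.scan.min_pct_cg,
                    config.seek.cpg_score, config.seek.threshold)
        results[inp.label] = {"length": L, "features": ft, "strands": {}}
        for rec in _strand_records(genome, config.strands):
            res = scan_one(rec, ft, config.scan, config.seek)
            results[inp.label]["strands"][rec.strand] = res
            stem = f"{inp.label}.{rec.strand}"
            _write_tsv(islands.island_report(res["islands"], L, ft),
                       outdir / f"{stem}.islands.tsv")
            _write_tsv(cpgseek.region_report(res["regions"], L, ft),
                       outdir / f"{stem}.regions.tsv")
            ann_rows = [{
                "start": a.interval.start, "end": a.interval.end,
                "cpg_count": a.cpg_count,
                "classification": a.classification,
                "features": ", ".join(a.features),
            } for a in res["annotations"]]
            _write_tsv(pd.DataFrame(
                ann_rows, columns=["start", "end", "cpg_count",
                                   "classification", "features"]),
                outdir / f"{stem}.annotations.tsv")
            dens = pd.DataFrame(
                [{"position": w.window_start + config.scan.window // 2,
                  "pct_cg": round(w.pct_cg, 4),
                  "obs_exp": round(w.obs_exp, 4)}
                 for w in res["profile"][::config.density_step]])
            _write_tsv(dens, outdir / f"{stem}.density.tsv")
    return results


def run_compare(config: RunConfig,
                results: dict[str, dict] | None = None,
                ) -> dict[str, pd.DataFrame]:
    """Build the comparative tables from scan results (re-scanning if needed)."""
    if results is None:
        results = run_scan(config)
    missing = [i.label for i in config.inputs if i.label not in results]
    if missing:
        raise InputFormatError(
            f"no scan results for species: {', '.join(missing)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # islands per strand, in reference coordinates (Table 2/3 analogue)
    island_rows = []
    for inp in config.inputs:
        L = results[inp.label]["length"]
        ft = results[inp.label]["features"]
        for strand, res in sorted(results[inp.label]["strands"].items()):
            rep = islands.island_report(res["islands"], L, ft)
            rep.insert(0, "species", inp.label)
            island_rows.append(rep)
    island_table = (pd.concat(island_rows, ignore_index=True)
                    if island_rows else pd.DataFrame(
                        columns=["species", "start", "end", "region", "length",
                                 "cg_sum", "pct_cg", "obs_exp", "strand"]))

    summaries = []
    ann_by_species: dict[str, dict[str, list]] = {}
    for inp in config.inputs:
        L = results[inp.label]["length"]
        per_strand = {strand: res["annotations"]
                      for strand, res in sorted(
                          results[inp.label]["strands"].items())}
        # fall back to bare region counts when no annotation was possible
        if all(not v for v in per_strand.values()):
            per_strand = {
                strand: [annotate.RegionAnnotation(
                    interval=r.interval if r.interval.frame == "reference"
                    else seqio.map_interval_to_reference(r.interval, L),
                    strand=strand, features=(), cpg_count=r.cpg_count,
                    classification="intergenic")
                    for r in res["regions"]]
                for strand, res in sorted(
                    results[inp.label]["strands"].items())}
        ann_by_species[inp.label] = per_strand
        summaries.append(annotate.build_summary(inp.label, per_strand,
                                                group=inp.group or None))
    if len(summaries) >= 2:
        cmp_tables = annotate.compare_species(summaries)
    else:
        cmp_tables = {"matrix": annotate.summary_frame(summaries),
                      "recurrent": pd.DataFrame(),
                      "strand_totals": pd.DataFrame(),
                      "group_means": pd.DataFrame()}
    multi = annotate.multi_feature_table(ann_by_species)

    island_table.to_csv(outdir / "islands_by_strand.tsv", sep="\t", index=False)
    cmp_tables["matrix"].to_csv(outdir / "cpg_counts_matrix.tsv", sep="\t")
    multi.to_csv(outdir / "multi_feature_regions.tsv", sep="\t", index=False)
    with open(outdir / "comparison.txt", "w") as fh:
        fh.write("CpG islands by strand\n")
        fh.write(island_table.to_string(index=False) + "\n\n")
        fh.write("CpG-site counts per feature\n")
        fh.write(cmp_tables["matrix"].to_string() + "\n\n")
        fh.write("Multi-feature regions\n")
        fh.write(multi.to_string(index=False) + "\n")
    return {"islands": island_table, "matrix": cmp_tables["matrix"],
            "multi": multi, "strand_totals": cmp_tables["strand_totals"],
            "group_means": cmp_tables["group_means"],
            "recurrent": cmp_tables["recurrent"]}
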