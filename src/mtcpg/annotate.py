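"""Attribute detections to mtDNA features and build comparative summaries.

Regions are attributed to every annotated feature they overlap by at least
1 bp.  A region overlapping two or more features is a multi-feature region:
it appears once in the multi-feature table and contributes its whole CpG
count to the strand total but not to any single gene's count — the same
separation the comparative tables draw between per-gene counts and
regions spanning gene boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from .cpgseek import CpGRegion, region_sites
from .seqio import Feature, FeatureTable, Interval, map_interval_to_reference

logger = logging.getLogger(__name__)

Classification = Literal["single_feature", "multi_feature", "intergenic"]

INTERGENIC = "intergenic region"


@dataclass(frozen=True)
class RegionAnnotation:
    interval: Interval  # reference frame
    strand: str
    features: tuple[str, ...]
    cpg_count: int
    classification: Classification


@dataclass
class SpeciesSummary:
    """Per-feature, per-strand CpG-site counts for one genome."""

    species: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    multi_counts: dict[str, int] = field(default_factory=dict)
    strand_totals: dict[str, int] = field(default_factory=dict)
    group: str | None = None


def overlap_features(iv: Interval, ft: FeatureTable) -> list[Feature]:
    """Features overlapping ``iv`` by >= 1 bp, in genomic order."""
    return ft.overlapping(iv)


def classify_regions(regions: Sequence[CpGRegion], ft: FeatureTable,
                     ) -> list[RegionAnnotation]:
    """Classify each region as single-feature, multi-feature or intergenic.

    H-strand regions (reversed frame) are mapped to reference coordinates
    first so gene labels match the annotation.
    """
    out = []
    for r in regions:
        iv = r.interval
        if iv.frame == "reversed":
            iv = map_interval_to_reference(iv, ft.genome_length)
        hits = ft.overlapping(iv)
        names = tuple(f.name for f in hits)
        if not hits or all(f.kind == "intergenic" for f in hits):
            cls: Classification = "intergenic"
        elif len(hits) >= 2:
            cls = "multi_feature"
        else:
            cls = "single_feature"
        out.append(RegionAnnotation(interval=iv, strand=r.strand,
                                    features=names, cpg_count=r.cpg_count,
                                    classification=cls))
    return out


def build_summary(species: str,
                  annotations: Mapping[str, Sequence[RegionAnnotation]],
                  group: str | None = None) -> SpeciesSummary:
    """Aggregate annotated regions of both strands into one summary.

    ``annotations`` maps strand label -> annotations for that strand.  Each
    region contributes exactly once: to its feature's cell when it is
    single-feature, to the intergenic row when it overlaps nothing, or to
    the multi-feature bucket otherwise.
    """
    s = SpeciesSummary(species=species, group=group)
    for strand, anns in annotations.items():
        total = 0
        for a in anns:
            total += a.cpg_count
            if a.classification == "single_feature":
                key = (a.features[0], strand)
                s.counts[key] = s.counts.get(key, 0) + a.cpg_count
            elif a.classification == "intergenic":
                key = (INTERGENIC, strand)
                s.counts[key] = s.counts.get(key, 0) + a.cpg_count
            else:
                s.multi_counts[strand] = s.multi_counts.get(strand, 0) + a.cpg_count
        s.strand_totals[strand] = total
    return s


def summary_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """Features x (species, strand) matrix of CpG-site counts."""
    feature_names: list[str] = []
    for s in summaries:
        for (name, _strand) in s.counts:
            if name not in feature_names:
                feature_names.append(name)
    columns = pd.MultiIndex.from_tuples(
        [(s.species, strand) for s in summaries
         for strand in sorted(s.strand_totals)],
        names=["species", "strand"])
    df = pd.DataFrame(0, index=feature_names, columns=columns, dtype=int)
    for s in summaries:
        for (name, strand), n in s.counts.items():
            df.loc[name, (s.species, strand)] = n
    multi = {(s.species, strand): s.multi_counts.get(strand, 0)
             for s in summaries for strand in sorted(s.strand_totals)}
    totals = {(s.species, strand): s.strand_totals.get(strand, 0)
              for s in summaries for strand in sorted(s.strand_totals)}
    df.loc["multi-feature regions"] = pd.Series(multi)
    df.loc["sum of all CpG sites/strand"] = pd.Series(totals)
    return df


def compare_species(summaries: Sequence[SpeciesSummary],
                    min_species: int = 7) -> dict[str, pd.DataFrame]:
    """Cross-species comparison: count matrix, recurrent features, group means.

    Features are aligned by canonical locus name; a feature populated in at
    least ``min_species`` species is flagged as recurrent (the analogue of
    the bold rows of comparative tables).  When summaries carry a
    vertebrate/invertebrate group label, per-group mean strand totals are
    reported.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two species to compare")
    vocab: dict[str, set[str]] = {}
    for s in summaries:
        for (name, _), _n in s.counts.items():
            vocab.setdefault(name, set()).add(s.species)
    unmatched = [n for n, sp in vocab.items() if len(sp) == 1]
    if unmatched:
        logger.warning("features seen in only one species: %s",
                       ", ".join(sorted(unmatched)))
    matrix = summary_frame(summaries)
    feature_rows = matrix.index[:-2]
    present = {}
    for name in feature_rows:
        n_sp = sum(
            1 for s in summaries
            if any(k[0] == name for k in s.counts))
        present[name] = n_sp
    recurrent = pd.DataFrame({
        "n_species": pd.Series(present),
    })
    recurrent["recurrent"] = recurrent["n_species"] >= min_species

    rows = []
    for s in summaries:
        for strand, tot in sorted(s.strand_totals.items()):
            rows.append({"species": s.species, "group": s.group or "",
                         "strand": strand, "total_cpg_sites": tot})
    totals = pd.DataFrame(rows)
    if totals["group"].str.len().gt(0).any():
        group_means = (totals.groupby(["group", "strand"])["total_cpg_sites"]
                       .mean().rename("mean_total").reset_index())
    else:
        group_means = pd.DataFrame(columns=["group", "strand", "mean_total"])
    return {"matrix": matrix, "recurrent": recurrent,
            "strand_totals": totals, "group_means": group_means}


def multi_feature_table(annotations_by_species: Mapping[
        str, Mapping[str, Sequence[RegionAnnotation]]]) -> pd.DataFrame:
    """One row per multi-feature (or intergenic) region across species."""
    rows = []
    for species, per_strand in annotations_by_species.items():
        for strand, anns in sorted(per_strand.items()):
            for a in anns:
                if a.classification == "single_feature":
                    continue
                label = ", ".join(a.features) if a.features else INTERGENIC
                rows.append({"species": species, "strand": strand,
                             "start": a.interval.start, "end": a.interval.end,
                             "cpg_count": a.cpg_count, "features": label})
    cols = ["species", "strand", "start", "end", "cpg_count", "features"]
    return pd.DataFrame(rows, columns=cols)


def conservation_check(annotations: Sequence[RegionAnnotation],
                       regions: Sequence[CpGRegion]) -> bool:
    """True when annotation preserves the strand's total CpG-site count."""
    return sum(a.cpg_count for a in annotations) == region_sites(regions)
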