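"""Sequence and annotation I/O, strand handling and coordinate mapping.

Mitochondrial reference sequences deposit the light (L) strand; the heavy
(H) strand is its reverse complement.  Detections made on the H strand live
in the reversed coordinate frame and are mapped back to reference (L-strand)
coordinates before they are compared with gene annotations.

All coordinates are 1-based inclusive, the convention of GenBank feature
tables and of the comparative mtDNA literature.  BED input/output converts
at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from ._names import canonical_name
from .errors import CoordinateError, InputFormatError

Strand = Literal["L", "H"]
Frame = Literal["reference", "reversed"]

_VALID_BASES = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomeRecord:
    """One strand of a (mitochondrial) genome sequence.

    ``strand`` records which biological strand the stored sequence
    represents; a freshly loaded reference is the L strand.
    """

    id: str
    sequence: str
    topology: Literal["linear", "circular"] = "linear"
    strand: Strand = "L"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputFormatError(f"{self.id}: zero-length sequence")


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive interval in either strand coordinate frame."""

    start: int
    end: int
    frame: Frame = "reference"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(f"bad interval {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Feature:
    """A named annotated locus (gene, tRNA, rRNA, D-loop, origin...)."""

    name: str
    kind: Literal["protein_gene", "tRNA", "rRNA", "noncoding",
                  "rep_origin", "intergenic"]
    start: int
    end: int
    strand: Strand = "L"
    wraps_origin: bool = False

    def spans(self, genome_length: int) -> list[tuple[int, int]]:
        """Linear spans covered by the feature (two when it wraps the origin)."""
        if self.wraps_origin:
            return [(self.start, genome_length), (1, self.end)]
        return [(self.start, self.end)]

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return self.end + genome_length - self.start + 1
        return self.end - self.start + 1


@dataclass
class FeatureTable:
    """Validated collection of features on one genome."""

    features: list[Feature]
    genome_length: int
    _tree: IntervalTree = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        bad = []
        for f in self.features:
            if not (1 <= f.start <= self.genome_length
                    and 1 <= f.end <= self.genome_length):
                bad.append(f)
            elif not f.wraps_origin and f.start > f.end:
                bad.append(f)
        if bad:
            names = ", ".join(f"{f.name}({f.start}..{f.end})" for f in bad)
            raise CoordinateError(
                f"features outside genome of length {self.genome_length}: {names}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        # half-open keys; data is the feature itself
        self._tree = IntervalTree()
        for f in self.features:
            for s, e in f.spans(self.genome_length):
                self._tree.addi(s, e + 1, f)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def overlapping(self, iv: Interval) -> list[Feature]:
        """Features overlapping ``iv`` by >= 1 bp, in genomic order.

        An origin-wrapping feature covers position 1 and therefore sorts
        first.
        """
        hits = {id(h.data): h.data for h in self._tree.overlap(iv.start, iv.end + 1)}
        return sorted(hits.values(),
                      key=lambda f: (min(s for s, _ in f.spans(self.genome_length)),
                                     f.end, f.name))


# ---------------------------------------------------------------------------
# sequence I/O

def _clean(seq: str) -> str:
    up = seq.upper()
    return "".join(c if c in _VALID_BASES else "N" for c in up)


def iter_fasta(path: str | Path,
               topology: Literal["linear", "circular"] = "linear",
               ) -> Iterator[GenomeRecord]:
    n = 0
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            n += 1
            seq = _clean(str(rec.seq))
            if not seq:
                raise InputFormatError(f"{path}: record {rec.id} has no sequence")
            yield GenomeRecord(id=rec.id, sequence=seq, topology=topology)
    except ValueError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc
    if n == 0:
        raise InputFormatError(f"{path}: no FASTA records found")


def read_fasta(path: str | Path,
               topology: Literal["linear", "circular"] = "linear",
               ) -> GenomeRecord:
    """Read the first (usually only) record of a FASTA file."""
    return next(iter_fasta(path, topology=topology))


def write_fasta(g: GenomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{g.id}\n")
        for i in range(0, g.length, width):
            fh.write(g.sequence[i:i + width] + "\n")


def reverse_complement(g: GenomeRecord) -> GenomeRecord:
    """Return the opposite strand (the ``revseq`` operation).

    The strand label flips L<->H; coordinates of anything detected on the
    returned record are in the reversed frame.
    """
    rc = str(Seq(g.sequence).reverse_complement())
    # Bio handles IUPAC codes; our sequences only carry ACGTN
    return replace(g, sequence=rc, strand="H" if g.strand == "L" else "L")


# ---------------------------------------------------------------------------
# coordinate mapping

def map_interval_to_reference(iv: Interval, genome_length: int) -> Interval:
    """Map an interval from the reversed (H-strand) frame to the reference frame."""
    if iv.frame != "reversed":
        raise CoordinateError("interval is not in the reversed frame")
    if iv.end > genome_length:
        raise CoordinateError(
            f"interval {iv.start}..{iv.end} outside genome of {genome_length} bp")
    return Interval(genome_length - iv.end + 1,
                    genome_length - iv.start + 1, frame="reference")


def map_interval_to_reversed(iv: Interval, genome_length: int) -> Interval:
    """Inverse of :func:`map_interval_to_reference`."""
    if iv.frame != "reference":
        raise CoordinateError("interval is not in the reference frame")
    if iv.end > genome_length:
        raise CoordinateError(
            f"interval {iv.start}..{iv.end} outside genome of {genome_length} bp")
    return Interval(genome_length - iv.end + 1,
                    genome_length - iv.start + 1, frame="reversed")


# ---------------------------------------------------------------------------
# feature I/O

_GENBANK_KINDS = {
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "CDS": "protein_gene",
    "gene": "protein_gene",
    "D-loop": "noncoding",
    "rep_origin": "rep_origin",
    "misc_feature": "noncoding",
}

_TSV_COLUMNS = ["name", "kind", "start", "end", "strand", "wraps_origin"]


def read_features(path: str | Path,
                  dialect: Literal["genbank", "bed", "tsv"],
                  genome_length: int | None = None) -> FeatureTable:
    """Read feature annotations in one of three dialects.

    ``genbank`` parses a flat file (genome length comes from the record);
    ``bed`` is 0-based half-open and converted on input; ``tsv`` is this
    package's 1-based six-column dialect.  ``genome_length`` is required for
    bed/tsv so coordinates can be validated.
    """
    if dialect == "genbank":
        return _read_genbank(path)
    if genome_length is None:
        raise InputFormatError(f"{dialect} annotations need genome_length")
    if dialect == "bed":
        return _read_bed(path, genome_length)
    if dialect == "tsv":
        return _read_tsv(path, genome_length)
    raise InputFormatError(f"unknown annotation dialect: {dialect}")


def _feature_name(quals: dict) -> str | None:
    for key in ("gene", "product", "standard_name", "note"):
        if key in quals and quals[key]:
            return canonical_name(str(quals[key][0]))
    return None


def _kind_for(ftype: str, name: str) -> str:
    if name.startswith("TRN"):
        return "tRNA"
    if name.endswith("rRNA"):
        return "rRNA"
    if name == "rep_origin":
        return "rep_origin"
    if name in ("D-LOOP", "AT-REGION"):
        return "noncoding"
    return _GENBANK_KINDS.get(ftype, "noncoding")


def _read_genbank(path: str | Path) -> FeatureTable:
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc
    length = len(rec.seq)
    feats: list[Feature] = []
    seen: set[tuple[str, int, int]] = set()
    for f in rec.features:
        if f.type not in _GENBANK_KINDS:
            continue
        name = _feature_name(dict(f.qualifiers))
        if name is None:
            name = "D-LOOP" if f.type == "D-loop" else (
                "rep_origin" if f.type == "rep_origin" else f.type)
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        start = int(min(int(p.start) for p in parts)) + 1
        end = int(max(int(p.end) for p in parts))
        wraps = False
        if len(f.location.parts) > 1:
            first, last = f.location.parts[0], f.location.parts[-1]
            if int(first.end) == length and int(last.start) == 0:
                wraps = True
                start = int(first.start) + 1
                end = int(last.end)
        strand: Strand = "H" if (f.location.strand or 1) < 0 else "L"
        kind = _kind_for(f.type, name)
        key = (name, start, end)
        if key in seen:
            continue
        seen.add(key)
        feats.append(Feature(name=name, kind=kind, start=start, end=end,
                             strand=strand, wraps_origin=wraps))
    return FeatureTable(feats, genome_length=length)


def _read_bed(path: str | Path, genome_length: int) -> FeatureTable:
    feats = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise InputFormatError(f"{path}:{ln}: fewer than 3 BED columns")
            start0, end0 = int(cols[1]), int(cols[2])
            name = canonical_name(cols[3]) if len(cols) > 3 else f"feature{ln}"
            strand: Strand = "H" if len(cols) > 5 and cols[5] == "-" else "L"
            feats.append(Feature(name=name, kind=_kind_for("gene", name),
                                 start=start0 + 1, end=end0, strand=strand))
    return FeatureTable(feats, genome_length=genome_length)


def _read_tsv(path: str | Path, genome_length: int) -> FeatureTable:
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != _TSV_COLUMNS[:4]:
            raise InputFormatError(
                f"{path}: expected columns {_TSV_COLUMNS}, got {header}")
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            row = dict(zip(header, cols))
            feats.append(Feature(
                name=canonical_name(row["name"]),
                kind=row["kind"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row.get("strand", "L") or "L",
                wraps_origin=row.get("wraps_origin", "").lower()
                in ("1", "true", "yes"),
            ))
    return FeatureTable(feats, genome_length=genome_length)


def write_features_tsv(ft: FeatureTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for f in ft:
            fh.write(f"{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\t"
                     f"{str(f.wraps_origin).lower()}\n")


def write_bed(intervals: Iterable[tuple[Interval, str]], chrom: str,
              path: str | Path) -> None:
    """Write (interval, name) pairs as 0-based half-open BED."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")
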