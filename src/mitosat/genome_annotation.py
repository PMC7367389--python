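"""Circular-genome data model and precise-annotation handling.

Coordinates are 1-based inclusive everywhere at the API surface. A feature
with ``end < start`` wraps the origin of the circle. Features flagged as
DNA regions are annotation overlays and are excluded from strand-coverage
accounting, which otherwise requires each strand to be tiled exactly once.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "CircularGenome",
    "AnnotationFeature",
    "AnnotationSet",
    "CoverageReport",
    "feature_length",
    "load_annotation_table",
    "write_annotation_table",
    "validate_strand_coverage",
    "extract_feature_sequence",
    "export_gff3",
    "read_genome_fasta",
    "write_genome_fasta",
]

_DNA_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA sequence with 1-based modular coordinates."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.id!r} contains non-ACGT characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence from ``start`` to ``end`` (1-based inclusive), wrapping
        the origin when ``end < start``."""
        n = self.length
        if not (1 <= start <= n and 1 <= end <= n):
            raise ValueError(
                f"coordinates ({start}, {end}) outside [1..{n}] for genome {self.id!r}"
            )
        if end >= start:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def base_at(self, pos: int) -> str:
        return self.fetch(pos, pos)


def feature_length(start: int, end: int, genome_length: int) -> int:
    """Length in bp of the 1-based inclusive interval [start, end] on a circle
    of ``genome_length`` bp; ``end < start`` wraps the origin."""
    if not (1 <= start <= genome_length and 1 <= end <= genome_length):
        raise ValueError(
            f"coordinates ({start}, {end}) outside [1..{genome_length}]"
        )
    if end >= start:
        return end - start + 1
    return (genome_length - start + 1) + end


@dataclass(frozen=True)
class AnnotationFeature:
    """One row of a precise-annotation table.

    ``dna_region`` marks annotation overlays (DNA regions) that do not take
    part in strand tiling; everything else is an RNA-level annotation.
    """

    name: str
    strand: str  # "+" (J / major coding strand) or "-" (N / minor)
    start: int
    end: int
    dna_region: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"feature {self.name!r}: coordinates must be >= 1")

    def length(self, genome_length: int) -> int:
        return feature_length(self.start, self.end, genome_length)

    def wraps_origin(self) -> bool:
        return self.end < self.start


@dataclass
class AnnotationSet:
    """An ordered collection of features over one circular genome."""

    genome_length: int
    features: list[AnnotationFeature] = field(default_factory=list)

    def __iter__(self) -> Iterator[AnnotationFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def by_name(self, name: str) -> AnnotationFeature:
        """First feature with the given name (names may repeat)."""
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def on_strand(self, strand: str, include_dna_regions: bool = True):
        return [
            f
            for f in self.features
            if f.strand == strand and (include_dna_regions or not f.dna_region)
        ]

    def feature_at(self, pos: int, strand: str | None = None) -> list[AnnotationFeature]:
        """All features covering the 1-based position ``pos``."""
        out = []
        for f in self.features:
            if strand is not None and f.strand != strand:
                continue
            if f.wraps_origin():
                covered = pos >= f.start or pos <= f.end
            else:
                covered = f.start <= pos <= f.end
            if covered:
                out.append(f)
        return out


class AnnotationParseError(ValueError):
    pass


class AnnotationValidationError(ValueError):
    pass


def load_annotation_table(path: str | Path, genome_length: int | None = None) -> AnnotationSet:
    """Read a precise-annotation TSV (Gene/Strand/Start/End/Length[/DNARegion]).

    The declared Length column is cross-checked against the length computed
    from the coordinates; the genome length defaults to the maximum annotated
    coordinate when not given.
    """
    path = Path(path)
    rows: list[tuple[int, dict]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"Gene", "Strand", "Start", "End", "Length"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise AnnotationParseError(
                f"{path}: header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            rows.append((lineno, row))

    features: list[AnnotationFeature] = []
    declared: list[int] = []
    max_coord = 0
    for lineno, row in rows:
        try:
            start = int(row["Start"].replace(",", ""))
            end = int(row["End"].replace(",", ""))
            length = int(row["Length"].replace(",", ""))
            strand = row["Strand"].strip()
            strand = {"J": "+", "N": "-"}.get(strand, strand)
            dna_region = bool((row.get("DNARegion") or "").strip())
            feat = AnnotationFeature(
                name=row["Gene"].strip(),
                strand=strand,
                start=start,
                end=end,
                dna_region=dna_region,
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise AnnotationParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
        features.append(feat)
        declared.append(length)
        max_coord = max(max_coord, start, end)

    n = genome_length if genome_length is not None else max_coord
    mismatches = []
    for feat, decl in zip(features, declared):
        computed = feat.length(n)
        if computed != decl:
            mismatches.append(f"{feat.name} ({feat.start}-{feat.end}): declared {decl}, computed {computed}")
    if mismatches:
        raise AnnotationValidationError(
            "declared vs computed length mismatch: " + "; ".join(mismatches)
        )
    return AnnotationSet(genome_length=n, features=features)


def write_annotation_table(ann: AnnotationSet, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["Gene", "Strand", "Start", "End", "Length", "DNARegion"])
        for f in ann.features:
            writer.writerow(
                [f.name, f.strand, f.start, f.end, f.length(ann.genome_length),
                 "*" if f.dna_region else ""]
            )


@dataclass
class CoverageReport:
    """Gaps and overlaps per strand among non-DNA-region features."""

    gaps: dict[str, list[tuple[int, int]]]
    overlaps: dict[str, list[tuple[int, int]]]

    @property
    def clean(self) -> bool:
        return not any(self.gaps.values()) and not any(self.overlaps.values())


def _coverage_counts(features: Iterable[AnnotationFeature], n: int):
    import numpy as np

    counts = np.zeros(n, dtype=np.int32)
    for f in features:
        if f.wraps_origin():
            counts[f.start - 1 :] += 1
            counts[: f.end] += 1
        else:
            counts[f.start - 1 : f.end] += 1
    return counts


def _runs(mask, n: int) -> list[tuple[int, int]]:
    """Maximal true runs of a boolean array as 1-based circular intervals."""
    import numpy as np

    if not mask.any():
        return []
    if mask.all():
        return [(1, n)]
    # rotate so the array starts on a False to make runs non-wrapping
    first_false = int(np.argmin(mask))
    rotated = np.roll(mask, -first_false)
    runs = []
    start = None
    for i, v in enumerate(rotated):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(rotated) - 1))
    out = []
    for s, e in runs:
        out.append(((s + first_false) % n + 1, (e + first_false) % n + 1))
    return sorted(out)


def validate_strand_coverage(ann: AnnotationSet) -> CoverageReport:
    """Check that non-DNA-region features tile each strand of the circle
    exactly once; uncovered and doubly covered intervals are reported, not
    raised."""
    gaps: dict[str, list[tuple[int, int]]] = {}
    overlaps: dict[str, list[tuple[int, int]]] = {}
    for strand in ("+", "-"):
        feats = ann.on_strand(strand, include_dna_regions=False)
        counts = _coverage_counts(feats, ann.genome_length)
        gaps[strand] = _runs(counts == 0, ann.genome_length)
        overlaps[strand] = _runs(counts >= 2, ann.genome_length)
    return CoverageReport(gaps=gaps, overlaps=overlaps)


def extract_feature_sequence(genome: CircularGenome, feat: AnnotationFeature) -> str:
    """Feature sequence 5'->3' on its own strand: the plus-strand subsequence
    for '+' features, its reverse complement for '-' features."""
    s = genome.fetch(feat.start, feat.end)
    if feat.strand == "-":
        return reverse_complement(s)
    return s


def export_gff3(ann: AnnotationSet, path: str | Path, seqid: str = "genome") -> None:
    """Write the annotation as GFF3; DNA-region overlays carry a
    ``dna_region=true`` attribute. Wrapping features keep their circular
    coordinates (start > end) with an ``Is_circular`` note."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {ann.genome_length}\n")
        for f in ann.features:
            attrs = [f"Name={f.name}"]
            if f.dna_region:
                attrs.append("dna_region=true")
            if f.wraps_origin():
                attrs.append("Is_circular=true")
            ftype = "region" if f.dna_region else "gene"
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "mitosat",
                        ftype,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_genome_fasta(path: str | Path) -> CircularGenome:
    record = next(SeqIO.parse(str(path), "fasta"))
    return CircularGenome(id=record.id, sequence=str(record.seq).upper())


def write_genome_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def rotate_origin(genome: CircularGenome, new_origin: int) -> CircularGenome:
    """Rotate the sequence so the 1-based position ``new_origin`` becomes 1."""
    n = genome.length
    if not 1 <= new_origin <= n:
        raise ValueError(f"new origin {new_origin} outside [1..{n}]")
    i = new_origin - 1
    return replace(genome, sequence=genome.sequence[i:] + genome.sequence[:i])
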