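"""Per-STR allele tables, the alternative-allele ratio and CNV selection.

The reference allele at an STR position is the most frequent expanded
allele. The alternative-allele ratio is the depth of all non-reference
alleles divided by the total depth at the position; positions whose ratio
exceeds the selection threshold (default 1%) are selected. Alleles are
classified as whole-unit CNV, substitution, other indel or deletion
placeholder; only whole-unit indels change the STR copy number.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from mitosat.pileup_io import (
    PLACEHOLDER_LABEL,
    AlleleDescriptor,
    AlleleFixtureRow,
    PileupColumn,
    expand_variant,
)
from mitosat.str_catalog import STRLocus

__all__ = [
    "AlleleTable",
    "STRVariantCall",
    "tabulate_alleles",
    "alt_allele_ratio",
    "classify_allele",
    "call_str_cnv",
    "calls_from_fixture_rows",
    "snp_scan",
    "left_normalize_columns",
    "write_calls_wide",
    "write_calls_long",
    "DEFAULT_SELECTION_THRESHOLD",
]

DEFAULT_SELECTION_THRESHOLD = 0.01

CLASS_CNV = "cnv_whole_unit"
CLASS_SUBSTITUTION = "substitution"
CLASS_OTHER = "other_indel"
CLASS_PLACEHOLDER = "placeholder"
CLASS_REFERENCE = "reference"


@dataclass
class AlleleTable:
    """Expanded alleles at one STR locus, ordered by depth (desc), ties by
    label. The first entry is the designated reference allele."""

    locus: STRLocus
    entries: list[tuple[str, int]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.entries

    @property
    def reference(self) -> str:
        if self.empty:
            raise ValueError(f"empty allele table at position {self.locus.position}")
        return self.entries[0][0]

    @property
    def reference_depth(self) -> int:
        return self.entries[0][1] if self.entries else 0

    @property
    def total_depth(self) -> int:
        return sum(d for _, d in self.entries)


def _sorted_entries(counts: Mapping[str, int]) -> list[tuple[str, int]]:
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def tabulate_alleles(
    columns: Iterable[PileupColumn], locus: STRLocus
) -> AlleleTable:
    """Aggregate the pileup column(s) at an STR position into an allele table.

    Single-column accounting: after left-normalization every allele of the
    array is tallied at the locus' first position, so only the column at
    ``locus.position`` contributes.
    """
    agg: Counter = Counter()
    for col in columns:
        if col.position != locus.position:
            continue
        for desc, count in col.allele_counts():
            agg[expand_variant(locus, desc)] += count
    return AlleleTable(locus=locus, entries=_sorted_entries(agg))


def left_normalize_columns(
    columns: Sequence[PileupColumn], loci: Sequence[STRLocus]
) -> list[PileupColumn]:
    """Move indel alleles reported anywhere inside an STR array to the
    array's first position (aligners place homopolymer indels at varying
    offsets)."""
    spans = {
        locus.position: range(locus.position, locus.position + locus.array_length)
        for locus in loci
    }
    moved: dict[int, Counter] = {p: Counter() for p in spans}
    out: list[PileupColumn] = []
    for col in columns:
        target = None
        for anchor, span in spans.items():
            if col.position in span and col.position != anchor:
                target = anchor
                break
        if target is None:
            out.append(col)
            continue
        keep = Counter()
        for label, count in col.counts.items():
            desc = AlleleDescriptor.from_label(label)
            if desc.kind in {"insertion", "deletion"}:
                moved[target][label] += count  # indel observations migrate
            else:
                keep[label] += count
        out.append(
            PileupColumn(
                chrom=col.chrom,
                position=col.position,
                ref_base=col.ref_base,
                depth=sum(keep.values()),
                counts=keep,
            )
        )
    final = []
    for col in out:
        extra = moved.get(col.position)
        if extra:
            merged = Counter(col.counts)
            merged.update(extra)
            col = PileupColumn(
                chrom=col.chrom,
                position=col.position,
                ref_base=col.ref_base,
                depth=sum(merged.values()),
                counts=merged,
            )
        final.append(col)
    return final


def alt_allele_ratio(table: AlleleTable) -> float:
    """(total depth - reference depth) / total depth, in [0, 1)."""
    total = table.total_depth
    if total == 0:
        raise ValueError(
            f"undefined alternative-allele ratio: zero depth at position "
            f"{table.locus.position}"
        )
    return (total - table.reference_depth) / total


def classify_allele(expanded: str, unit: str) -> str:
    """Class of an expanded allele string relative to the repeat unit."""
    if expanded == PLACEHOLDER_LABEL:
        return CLASS_PLACEHOLDER
    if expanded.startswith("["):
        return CLASS_CNV
    if len(expanded) == 1 and expanded in "ACGTN":
        return CLASS_SUBSTITUTION
    return CLASS_OTHER


@dataclass
class STRVariantCall:
    """Selection decision and per-allele classification at one STR locus."""

    locus: STRLocus
    gene: str
    table: AlleleTable
    alt_ratio: float
    selected: bool
    threshold: float
    classes: list[str] = field(default_factory=list)

    @property
    def reference_label(self) -> str:
        return self.table.reference

    def cnv_alleles(self) -> list[tuple[str, int]]:
        return [
            (a, d)
            for (a, d), cls in zip(self.table.entries[1:], self.classes[1:])
            if cls == CLASS_CNV
        ]

    def substitution_alleles(self) -> list[tuple[str, int]]:
        return [
            (a, d)
            for (a, d), cls in zip(self.table.entries[1:], self.classes[1:])
            if cls == CLASS_SUBSTITUTION
        ]


def _call_from_table(
    table: AlleleTable, gene: str, threshold: float
) -> STRVariantCall:
    ratio = alt_allele_ratio(table)
    classes = [CLASS_REFERENCE] + [
        classify_allele(a, table.locus.unit) for a, _ in table.entries[1:]
    ]
    return STRVariantCall(
        locus=table.locus,
        gene=gene,
        table=table,
        alt_ratio=ratio,
        selected=ratio > threshold,
        threshold=threshold,
        classes=classes,
    )


def call_str_cnv(
    catalog: Sequence[STRLocus],
    columns: Sequence[PileupColumn],
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
    annotation=None,
    normalize: bool = True,
) -> list[STRVariantCall]:
    """Build one variant call per catalog locus from pileup columns."""
    if columns:
        chroms = {c.chrom for c in columns}
        if len(chroms) > 1:
            raise ValueError(f"pileup mixes chromosomes: {sorted(chroms)}")
    if normalize:
        columns = left_normalize_columns(columns, catalog)
    by_pos: dict[int, list[PileupColumn]] = {}
    for col in columns:
        by_pos.setdefault(col.position, []).append(col)
    calls = []
    for locus in catalog:
        gene = ""
        if annotation is not None:
            names = [
                f.name
                for f in annotation.feature_at(locus.position)
                if not f.dna_region
            ]
            gene = ";".join(names)
        table = tabulate_alleles(by_pos.get(locus.position, []), locus)
        if table.empty:
            calls.append(
                STRVariantCall(
                    locus=locus,
                    gene=gene,
                    table=table,
                    alt_ratio=0.0,
                    selected=False,
                    threshold=threshold,
                    classes=[],
                )
            )
            continue
        calls.append(_call_from_table(table, gene, threshold))
    return calls


def calls_from_fixture_rows(
    rows: Sequence[AlleleFixtureRow],
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
) -> list[STRVariantCall]:
    """Variant calls straight from the packaged allele-depth fixture; allele
    labels are expanded against each row's reference STR."""
    calls = []
    for row in rows:
        counts: Counter = Counter()
        for label, depth in zip(row.labels, row.depths):
            if label == "Ref":
                expanded = expand_variant(row.ref, AlleleDescriptor("reference_match"))
            else:
                expanded = expand_variant(row.ref, AlleleDescriptor.from_label(label))
            counts[expanded] += depth
        table = AlleleTable(locus=row.ref, entries=_sorted_entries(counts))
        calls.append(_call_from_table(table, row.gene, threshold))
    return calls


def snp_scan(
    calls: Sequence[STRVariantCall],
    per_allele_threshold: float = DEFAULT_SELECTION_THRESHOLD,
) -> list[tuple[int, str, int, float]]:
    """Substitution alleles whose individual frequency is >= the threshold,
    as (position, base, depth, frequency) tuples."""
    hits = []
    for call in calls:
        total = call.table.total_depth
        if total == 0:
            continue
        for base, depth in call.substitution_alleles():
            freq = depth / total
            if freq >= per_allele_threshold:
                hits.append((call.locus.position, base, depth, freq))
    return hits


def write_calls_wide(
    calls: Sequence[STRVariantCall], path: str | Path, header_comment: str | None = None
) -> None:
    """Wide table: one row per position with slash-separated allele and
    depth lists (the published layout)."""
    with Path(path).open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("Position\tGene\tRef\tAllele\tDepth\tAltRatio\tSelected\n")
        for call in calls:
            if call.table.empty:
                fh.write(
                    f"{call.locus.position}\t{call.gene}\t{call.locus.label()}\t"
                    f"\t\tNA\t0\n"
                )
                continue
            labels, depths = [], []
            for allele, depth in call.table.entries:
                labels.append("Ref" if allele == call.reference_label else allele)
                depths.append(str(depth))
            fh.write(
                f"{call.locus.position}\t{call.gene}\t{call.reference_label}\t"
                f"{'/'.join(labels)}\t{'/'.join(depths)}\t"
                f"{call.alt_ratio:.6f}\t{int(call.selected)}\n"
            )


def write_calls_long(
    calls: Sequence[STRVariantCall], path: str | Path, header_comment: str | None = None
) -> None:
    """Long table: one allele per row with class and per-allele frequency."""
    with Path(path).open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("Position\tGene\tRef\tAllele\tClass\tDepth\tFrequency\tAltRatio\tSelected\n")
        for call in calls:
            if call.table.empty:
                continue
            total = call.table.total_depth or 1
            for (allele, depth), cls in zip(call.table.entries, call.classes):
                fh.write(
                    f"{call.locus.position}\t{call.gene}\t{call.reference_label}\t"
                    f"{allele}\t{cls}\t{depth}\t{depth / total:.6f}\t"
                    f"{call.alt_ratio:.6f}\t{int(call.selected)}\n"
                )
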