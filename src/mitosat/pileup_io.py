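"""samtools pileup dialect: parsing, writing and STR allele expansion.

The bases field of a pileup column encodes '.'/',' for a reference match,
ACGT/acgt for a substitution, '+LEN<seq>'/'-LEN<seq>' insertion/deletion
labels, '*' for a base consumed by an upstream deletion, '^q' read-start
marks (the mapping-quality byte is skipped) and '$' read ends. In this
dialect every indel label is one observation in its own right — the depth
column is the sum over all allele labels including indels, matching the
published per-position allele/depth tables.

Allele labels are normalized to ASCII upper case: "+1G", "-2AA", "G", "*".
"""

from __future__ import annotations

import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from mitosat.str_catalog import STRLocus, format_str, parse_str

__all__ = [
    "AlleleDescriptor",
    "PileupColumn",
    "PileupParseError",
    "parse_pileup_line",
    "read_pileup",
    "write_pileup",
    "format_pileup_column",
    "expand_variant",
    "normalize_allele_label",
    "read_allele_fixture",
    "REF_LABEL",
    "PLACEHOLDER_LABEL",
]

REF_LABEL = "Ref"
PLACEHOLDER_LABEL = "*"


class PileupParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleDescriptor:
    """One allele observed at a pileup column, in canonical text form."""

    kind: str  # reference_match | substitution | insertion | deletion | deletion_placeholder
    sequence: str = ""  # inserted/deleted bases, or the substituted base
    label: str = ""

    KINDS = frozenset(
        {"reference_match", "substitution", "insertion", "deletion", "deletion_placeholder"}
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown allele kind {self.kind!r}")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.kind == "reference_match":
            return REF_LABEL
        if self.kind == "substitution":
            return self.sequence
        if self.kind == "insertion":
            return f"+{len(self.sequence)}{self.sequence}"
        if self.kind == "deletion":
            return f"-{len(self.sequence)}{self.sequence}"
        return PLACEHOLDER_LABEL

    @classmethod
    def from_label(cls, label: str) -> "AlleleDescriptor":
        """Inverse of ``label``: parse a canonical allele label."""
        label = normalize_allele_label(label)
        if label == REF_LABEL:
            return cls("reference_match")
        if label == PLACEHOLDER_LABEL:
            return cls("deletion_placeholder")
        if label[0] in "+-":
            body = label[1:]
            i = 0
            while i < len(body) and body[i].isdigit():
                i += 1
            if i == 0 or not body[i:]:
                raise PileupParseError(f"malformed indel label {label!r}")
            length, seq = int(body[:i]), body[i:]
            if length != len(seq) or set(seq) - set("ACGTN"):
                raise PileupParseError(f"malformed indel label {label!r}")
            kind = "insertion" if label[0] == "+" else "deletion"
            return cls(kind, seq)
        if len(label) == 1 and label in "ACGTN":
            return cls("substitution", label)
        raise PileupParseError(f"malformed allele label {label!r}")


def normalize_allele_label(label: str) -> str:
    """Collapse typeset artifacts: Unicode minus/dashes to '-', interior
    spaces removed, upper-cased."""
    label = unicodedata.normalize("NFKC", label.strip())
    for dash in ("−", "–", "—"):
        label = label.replace(dash, "-")
    label = label.replace(" ", "")
    if label.lower() == "ref":
        return REF_LABEL
    return label.upper()


@dataclass
class PileupColumn:
    """One parsed pileup line: position, reference base, per-allele counts."""

    chrom: str
    position: int
    ref_base: str
    depth: int
    counts: Counter = field(default_factory=Counter)  # label -> count
    forward_counts: Counter = field(default_factory=Counter)  # strand metadata

    def allele_counts(self) -> list[tuple[AlleleDescriptor, int]]:
        return [
            (AlleleDescriptor.from_label(lbl), cnt)
            for lbl, cnt in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]

    def total(self) -> int:
        return sum(self.counts.values())


def parse_pileup_line(line: str) -> PileupColumn:
    """Decode one tab-separated pileup line (qualities column optional)."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise PileupParseError(f"pileup line has {len(fields)} fields, expected >= 5")
    chrom, pos_s, ref, depth_s, bases = fields[:5]
    try:
        position, depth = int(pos_s), int(depth_s)
    except ValueError as exc:
        raise PileupParseError(f"bad position/depth in line: {line!r}") from exc

    counts: Counter = Counter()
    forward: Counter = Counter()

    def tally(label: str, fwd: bool) -> None:
        counts[label] += 1
        if fwd:
            forward[label] += 1

    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(f"dangling '^' at offset {i} in bases field")
            i += 2  # skip mapping-quality byte
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"indel marker without length at offset {i}")
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length]
            if len(seq) != length:
                raise PileupParseError(
                    f"indel sequence shorter than declared length at offset {i}"
                )
            tally(f"{c}{length}{seq.upper()}", seq == seq.upper())
            i = j + length
            continue
        if c in ".,":
            tally(REF_LABEL, c == ".")
        elif c == "*":
            tally(PLACEHOLDER_LABEL, True)
        elif c.upper() in "ACGTN":
            tally(c.upper(), c.isupper())
        else:
            raise PileupParseError(f"unexpected character {c!r} at offset {i}")
        i += 1

    col = PileupColumn(
        chrom=chrom,
        position=position,
        ref_base=ref.upper(),
        depth=depth,
        counts=counts,
        forward_counts=forward,
    )
    if col.total() != depth:
        raise PileupParseError(
            f"{chrom}:{position}: allele counts sum to {col.total()}, depth is {depth}"
        )
    return col


def read_pileup(path: str | Path) -> Iterator[PileupColumn]:
    with Path(path).open() as fh:
        for line in fh:
            if line.strip():
                yield parse_pileup_line(line)


def format_pileup_column(col: PileupColumn) -> str:
    """Encode a column back into pileup text (deterministic label order)."""
    parts: list[str] = []
    for label in sorted(col.counts):
        count = col.counts[label]
        desc = AlleleDescriptor.from_label(label)
        for _ in range(count):
            if desc.kind == "reference_match":
                parts.append(".")
            elif desc.kind == "substitution":
                parts.append(desc.sequence)
            elif desc.kind == "deletion_placeholder":
                parts.append("*")
            else:
                sign = "+" if desc.kind == "insertion" else "-"
                parts.append(f"{sign}{len(desc.sequence)}{desc.sequence}")
    bases = "".join(parts)
    depth = col.total()
    quals = "~" * depth
    return f"{col.chrom}\t{col.position}\t{col.ref_base}\t{depth}\t{bases}\t{quals}"


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for col in columns:
            fh.write(format_pileup_column(col) + "\n")


def expand_variant(ref_str: STRLocus, allele: AlleleDescriptor) -> str:
    """Express a pileup allele relative to a reference STR.

    Whole-unit insertions/deletions become a new bracketed STR form
    ``[unit]n'``; anything else (substitutions, off-unit indels, deletion
    placeholders) keeps its raw label. The reference match becomes the
    reference bracketed form.
    """
    unit, n, m = ref_str.unit, ref_str.copies, ref_str.unit_length
    if allele.kind == "reference_match":
        return format_str(unit, n)
    if allele.kind in {"insertion", "deletion"}:
        seq = allele.sequence
        k, r = divmod(len(seq), m)
        if r == 0 and seq == unit * k:
            if allele.kind == "insertion":
                return format_str(unit, n + k)
            if k >= n:
                raise ValueError(
                    f"deletion of {k} units exceeds array of {n} copies at "
                    f"position {ref_str.position}"
                )
            return format_str(unit, n - k)
    return allele.label


def is_whole_unit_cnv(ref_str: STRLocus, allele: AlleleDescriptor) -> bool:
    if allele.kind not in {"insertion", "deletion"}:
        return False
    seq = allele.sequence
    m = ref_str.unit_length
    k, r = divmod(len(seq), m)
    return r == 0 and k >= 1 and seq == ref_str.unit * k


def copy_number_change(ref_str: STRLocus, allele: AlleleDescriptor) -> int:
    """Signed copy-number delta for a whole-unit CNV allele."""
    if not is_whole_unit_cnv(ref_str, allele):
        raise ValueError(f"{allele.label} is not a whole-unit CNV of {ref_str.label()}")
    k = len(allele.sequence) // ref_str.unit_length
    return k if allele.kind == "insertion" else -k


@dataclass
class AlleleFixtureRow:
    """One row of the packaged allele-depth table: a reference STR with its
    observed allele labels and depths."""

    position: int
    gene: str
    ref: STRLocus
    labels: list[str]
    depths: list[int]


def read_allele_fixture(path: str | Path) -> list[AlleleFixtureRow]:
    """Read the TSV mirror of the published per-position allele/depth table
    (columns Position, Gene, Ref, Allele, Depth; slash-separated lists)."""
    rows: list[AlleleFixtureRow] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                position = int(parts[idx["Position"]])
                gene = parts[idx["Gene"]]
                unit, copies = parse_str(normalize_allele_label(parts[idx["Ref"]]))
                labels = [
                    normalize_allele_label(t) for t in parts[idx["Allele"]].split("/")
                ]
                depths = [
                    int(t.replace(",", "")) for t in parts[idx["Depth"]].split("/")
                ]
            except (KeyError, IndexError, ValueError) as exc:
                raise PileupParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if len(labels) != len(depths):
                raise PileupParseError(
                    f"{path}:{lineno}: {len(labels)} alleles but {len(depths)} depths"
                )
            rows.append(
                AlleleFixtureRow(
                    position=position,
                    gene=gene,
                    ref=STRLocus(position=position, unit=unit, copies=copies),
                    labels=labels,
                    depths=depths,
                )
            )
    return rows


def fixture_row_to_column(row: AlleleFixtureRow, chrom: str = "mt") -> PileupColumn:
    """Re-express a fixture row as a pileup column (reference label kept as
    a reference match; all other labels parsed through the allele grammar)."""
    counts: Counter = Counter()
    for label, depth in zip(row.labels, row.depths):
        desc = (
            AlleleDescriptor("reference_match")
            if label == REF_LABEL
            else AlleleDescriptor.from_label(label)
        )
        counts[desc.label] += depth
    return PileupColumn(
        chrom=chrom,
        position=row.position,
        ref_base=row.ref.unit[0],
        depth=sum(row.depths),
        counts=counts,
    )
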