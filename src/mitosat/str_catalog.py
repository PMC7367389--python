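"""Short tandem repeat cataloguing.

An STR locus is a maximal run of a primitive repeat unit of length ``m``
repeated ``n`` times; homopolymers are the ``m = 1`` case. The locus
position is the genomic position of the first nucleotide of the reference
array, and loci are classified with the "m x n" label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from mitosat.genome_annotation import AnnotationSet, reverse_complement

__all__ = [
    "STRLocus",
    "find_strs",
    "format_str",
    "parse_str",
    "classify_str",
    "canonical_unit",
    "write_catalog",
    "read_catalog",
    "DEFAULT_MIN_COPIES",
    "DEFAULT_MIN_ARRAY_LEN",
]

# Defaults chosen so every locus of the published 20-position table is
# recovered: homopolymers need >= 5 copies, longer units >= 3 copies and
# >= 8 bp of array.
DEFAULT_MIN_COPIES: dict[int, int] = {1: 5}
DEFAULT_MIN_COPIES_LONG = 3
DEFAULT_MIN_ARRAY_LEN = 8
DEFAULT_MAX_UNIT_LEN = 6


def _is_primitive(unit: str) -> bool:
    """True when the unit is not a whole-number repetition of a shorter word."""
    m = len(unit)
    for d in range(1, m):
        if m % d == 0 and unit[:d] * (m // d) == unit:
            return False
    return True


@dataclass(frozen=True, order=True)
class STRLocus:
    """A maximal primitive-unit tandem repeat at a fixed genomic position."""

    position: int  # 1-based position of the first nucleotide of the array
    unit: str
    copies: int

    def __post_init__(self) -> None:
        if not self.unit or set(self.unit) - set("ACGT"):
            raise ValueError(f"invalid repeat unit {self.unit!r}")
        if not _is_primitive(self.unit):
            raise ValueError(f"repeat unit {self.unit!r} is not primitive")
        if self.copies < 2:
            raise ValueError("an STR needs at least 2 copies")

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def array_length(self) -> int:
        """Total array span in bp (unit length times copy number)."""
        return len(self.unit) * self.copies

    @property
    def end(self) -> int:
        return self.position + self.array_length - 1

    def label(self) -> str:
        return format_str(self.unit, self.copies)

    def mxn(self) -> str:
        return classify_str(self)


def format_str(unit: str, copies: int) -> str:
    """Bracketed notation, e.g. ('AT', 5) -> '[AT]5'."""
    return f"[{unit}]{copies}"


_STR_RE = re.compile(r"^\[([ACGT]+)\]_?(\d+)_?$")


def parse_str(text: str) -> tuple[str, int]:
    """Parse '[AT]5' or '[AT]_5_' into (unit, copies)."""
    m = _STR_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse STR notation {text!r}")
    return m.group(1), int(m.group(2))


def classify_str(locus: STRLocus) -> str:
    return f"{locus.unit_length} x {locus.copies}"


def canonical_unit(unit: str) -> str:
    """Lexicographically minimal rotation, for cross-locus unit comparison."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _min_copies_for(m: int, min_copies_by_unit_len: Mapping[int, int]) -> int:
    return min_copies_by_unit_len.get(
        m, DEFAULT_MIN_COPIES_LONG if m > 1 else DEFAULT_MIN_COPIES[1]
    )


def find_strs(
    seq: str,
    circular: bool = False,
    min_copies_by_unit_len: Mapping[int, int] | None = None,
    min_array_len: int = DEFAULT_MIN_ARRAY_LEN,
    max_unit_len: int = DEFAULT_MAX_UNIT_LEN,
) -> list[STRLocus]:
    """Scan for all maximal primitive-unit tandem repeats.

    Parameters
    ----------
    seq:
        Upper-case DNA string. With ``circular=True`` runs crossing the
        origin are found and reported once, anchored at their (1-based)
        circular start position.
    min_copies_by_unit_len:
        Minimum copy number keyed by unit length (default: 5 for 1-mers,
        3 otherwise). ``min_array_len`` additionally applies to units of
        length >= 2.
    """
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be upper-case ACGT")
    if min_copies_by_unit_len is None:
        min_copies_by_unit_len = DEFAULT_MIN_COPIES

    n = len(seq)
    # doubled string covers every origin-crossing run exactly once when run
    # starts are restricted to the first copy
    work = seq + seq if circular else seq
    loci: list[STRLocus] = []
    seen: set[tuple[int, str]] = set()

    for m in range(1, min(max_unit_len, n) + 1):
        limit = len(work) - m
        i = 0
        # match[j] true when work[j] == work[j+m]; maximal match stretches of
        # length t give a period-m region of t+m bases starting at the stretch
        # start.
        j = 0
        while j < limit:
            if work[j] != work[j + m]:
                j += 1
                continue
            start = j
            while j < limit and work[j] == work[j + m]:
                j += 1
            region_len = (j - start) + m
            if circular and start >= n:
                continue
            copies = region_len // m
            if circular:
                copies = min(copies, n // m)  # cannot exceed one full circle
            if copies < 2:
                continue
            unit = work[start : start + m]
            if not _is_primitive(unit):
                continue  # reported at the smaller true period
            loci.append(STRLocus(position=start + 1, unit=unit, copies=copies))

    if circular:
        loci = _dedupe_circular(loci, n)

    out = []
    for locus in loci:
        m = locus.unit_length
        if locus.copies < _min_copies_for(m, min_copies_by_unit_len):
            continue
        if m >= 2 and locus.array_length < min_array_len:
            continue
        key = (locus.position, locus.unit)
        if key in seen:
            continue
        seen.add(key)
        out.append(locus)
    out.sort(key=lambda l: (l.position, l.unit_length))
    return out


def _dedupe_circular(loci: list[STRLocus], n: int) -> list[STRLocus]:
    """Drop runs that are circular-rotation duplicates of an origin-crossing
    run with the same period."""
    wrapping = [l for l in loci if l.end > n]
    if not wrapping:
        return loci
    kept = []
    for locus in loci:
        duplicate = False
        for w in wrapping:
            if locus is w or locus.unit_length != w.unit_length:
                continue
            # positions covered by w, modulo n
            w_start0 = w.position - 1
            offset = (locus.position - 1 - w_start0) % n
            if offset + locus.array_length <= w.array_length:
                duplicate = True
                break
        if not duplicate:
            kept.append(locus)
    return kept


def write_catalog(
    loci: Sequence[STRLocus],
    path: str | Path,
    annotation: AnnotationSet | None = None,
    header_comment: str | None = None,
) -> None:
    """TSV catalog: position, unit, copies, class, gene (if annotation given)."""
    with Path(path).open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("Position\tUnit\tCopies\tSTR\tClass\tGene\n")
        for locus in loci:
            gene = ""
            if annotation is not None:
                hits = [
                    f.name
                    for f in annotation.feature_at(locus.position)
                    if not f.dna_region
                ]
                gene = ";".join(hits)
            fh.write(
                f"{locus.position}\t{locus.unit}\t{locus.copies}\t"
                f"{locus.label()}\t{locus.mxn()}\t{gene}\n"
            )


def read_catalog(path: str | Path) -> list[STRLocus]:
    loci = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("Position"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            loci.append(
                STRLocus(position=int(parts[0]), unit=parts[1], copies=int(parts[2]))
            )
    return loci


def locus_on_reverse_complement(locus: STRLocus, n: int) -> STRLocus:
    """Image of a locus under reverse complement of a length-``n`` sequence.

    The mirrored array occupies positions ``n - end + 1 .. n - position + 1``
    and its unit is the reverse complement of the original unit. When the
    original maximal repeat region carries a partial trailing unit the scanner
    anchors the mirrored locus up to ``m - 1`` bases further left; callers
    comparing catalogs should allow that phase shift.
    """
    return STRLocus(
        position=n - locus.end + 1,
        unit=reverse_complement(locus.unit),
        copies=locus.copies,
    )
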