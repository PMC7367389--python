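"""Tandem-repeat array decomposition and inverted-repeat element detection.

Long tandem-repeat arrays are decomposed against a library of named repeat
units (e.g. 28/34/44-bp unit types), allowing hybrid arrays and one partial
trailing unit. A transposon-like element is a pair of reverse-complementary
repeat arrays (inverted repeats) flanking an insert segment; read-level
support for the inverted configuration is counted with junction k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from mitosat.genome_annotation import (
    AnnotationSet,
    CircularGenome,
    reverse_complement,
)

__all__ = [
    "UnitLibrary",
    "ArrayDecomposition",
    "TransposonLikeElement",
    "decompose_array",
    "revcomp_unit_match",
    "find_ir_elements",
    "element_from_annotation",
    "inversion_junction_support",
    "invert_element",
    "consensus_decomposition",
]


@dataclass
class UnitLibrary:
    """Named repeat-unit sequences, e.g. {"R28": ..., "R34": ..., "R44": ...}."""

    units: dict[str, str]

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("unit library is empty")
        for name, seq in self.units.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"unit {name!r} has an invalid sequence")

    def items(self):
        return self.units.items()

    @classmethod
    def from_fasta(cls, path: str | Path) -> "UnitLibrary":
        from Bio import SeqIO

        units = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(units)

    def to_fasta(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for name, seq in self.units.items():
                fh.write(f">{name}\n{seq}\n")

    def reverse_complemented(self, suffix: str = "_rc") -> "UnitLibrary":
        return UnitLibrary(
            {f"{n}{suffix}": reverse_complement(s) for n, s in self.units.items()}
        )


@dataclass
class ArrayDecomposition:
    """Run-length decomposition of an array into library unit types."""

    blocks: list[tuple[str, int]]  # (unit type name, copies)
    partial: str = ""  # trailing partial unit sequence, if any
    partial_type: str = ""

    @property
    def has_partial(self) -> bool:
        return bool(self.partial)

    def pattern(self) -> str:
        """Human-readable pattern, e.g. '[R34]2-[R28]3-[R34]1'."""
        parts = [f"[{t}]{c}" for t, c in self.blocks]
        if self.has_partial:
            parts.append(f"[{self.partial_type}]partial")
        return "-".join(parts)

    def counted_copies(self) -> int:
        """Total copy number with a partial trailing unit counted as 1."""
        return sum(c for _, c in self.blocks) + (1 if self.has_partial else 0)

    def reconstruct(self, lib: UnitLibrary) -> str:
        return (
            "".join(lib.units[t] * c for t, c in self.blocks) + self.partial
        )


class DecompositionError(ValueError):
    pass


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def decompose_array(
    seq: str, lib: UnitLibrary, max_mismatch_per_unit: int = 0
) -> ArrayDecomposition:
    """Greedy left-to-right decomposition of ``seq`` into library units.

    At each offset the longest unit matching within the mismatch budget is
    consumed; at most one partial unit (a unit prefix) is allowed at the
    array end. Unmatchable sequence raises with the failing offset.
    """
    if not seq:
        raise DecompositionError("empty array sequence")
    ordered = sorted(lib.items(), key=lambda kv: -len(kv[1]))
    blocks: list[tuple[str, int]] = []
    partial = ""
    partial_type = ""
    i, n = 0, len(seq)
    while i < n:
        matched = None
        for name, unit in ordered:
            if i + len(unit) <= n and _mismatches(
                seq[i : i + len(unit)], unit
            ) <= max_mismatch_per_unit:
                matched = name
                i += len(unit)
                break
        if matched is not None:
            if blocks and blocks[-1][0] == matched:
                blocks[-1] = (matched, blocks[-1][1] + 1)
            else:
                blocks.append((matched, 1))
            continue
        # try a trailing partial unit (prefix of some unit, mismatch-budgeted)
        rest = seq[i:]
        for name, unit in ordered:
            if len(rest) < len(unit) and _mismatches(
                rest, unit[: len(rest)]
            ) <= max_mismatch_per_unit:
                partial, partial_type = rest, name
                i = n
                break
        else:
            raise DecompositionError(f"array unmatchable at offset {i}")
    dec = ArrayDecomposition(blocks=blocks, partial=partial, partial_type=partial_type)
    if max_mismatch_per_unit == 0:
        assert dec.reconstruct(lib) == seq  # exact reconstruction identity
    return dec


def _is_rotation(a: str, b: str) -> bool:
    return len(a) == len(b) and a in b + b


def revcomp_unit_match(
    left_units: Sequence[str], right_units: Sequence[str]
) -> tuple[bool, list[int]]:
    """True when every left unit is the reverse complement of some right
    unit up to rotation of the unit phase; per-left-unit offsets into the
    right list are returned (-1 on failure)."""
    offsets = []
    ok = True
    for lu in left_units:
        rc = reverse_complement(lu)
        hit = -1
        for j, ru in enumerate(right_units):
            if _is_rotation(rc, ru):
                hit = j
                break
        if hit < 0:
            ok = False
        offsets.append(hit)
    return ok, offsets


@dataclass(frozen=True)
class TransposonLikeElement:
    """Inverted-repeat pair flanking an insert segment (1-based inclusive)."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    orientation: str = "reference"  # or "inverted"
    insert_genes: tuple[str, ...] = ()

    @property
    def insert_start(self) -> int:
        return self.left_end + 1

    @property
    def insert_end(self) -> int:
        return self.right_start - 1

    def ir_length(self) -> int:
        return self.left_end - self.left_start + 1


def _composite_or_antisense(name: str) -> bool:
    if name.startswith(("HAS", "LAS", "Intergenic")):
        return True
    head = name.split("/")[0]
    return head.endswith("AS")


def element_from_annotation(
    ann: AnnotationSet,
    left_name: str = "R2",
    right_name: str = "R1",
    genome: CircularGenome | None = None,
) -> TransposonLikeElement:
    """Build the element directly from annotated repeat features; the insert
    is the ordered list of primary (non-composite, non-antisense) genes
    strictly between the two repeat arrays."""
    left = ann.by_name(left_name)
    right = ann.by_name(right_name)
    genes = []
    for f in sorted(ann.features, key=lambda f: f.start):
        if f.dna_region or f.name in {left_name, right_name}:
            continue
        if _composite_or_antisense(f.name):
            continue
        # overlap with the open insert interval: annotated repeats may
        # overhang neighbouring genes by a few bases
        if f.end > left.end and f.start < right.start and not f.wraps_origin():
            genes.append(f.name)
    if genome is not None:
        left_seq = genome.fetch(left.start, left.end)
        right_seq = genome.fetch(right.start, right.end)
        ok, _ = revcomp_unit_match([left_seq], [right_seq])
        # arrays may differ in copy number; fall back to unit-level check
        if not ok and reverse_complement(left_seq) != right_seq:
            pass  # copy numbers may differ within one element: undetermined
    return TransposonLikeElement(
        left_start=left.start,
        left_end=left.end,
        right_start=right.start,
        right_end=right.end,
        insert_genes=tuple(genes),
    )


def find_ir_elements(
    genome: CircularGenome,
    annotation: AnnotationSet | None = None,
    min_ir_len: int = 30,
    max_ir_mismatch: int = 0,
    min_insert: int = 1,
    seed_k: int = 12,
) -> list[TransposonLikeElement]:
    """Scan the genome for maximal reverse-complementary repeat pairs
    flanking an insert (inverted-repeat elements).

    Seeds are k-mers whose reverse complement recurs downstream; seeds are
    extended maximally in both directions and overlapping hits are merged.
    With an annotation, each element's insert is reported as the ordered
    primary gene list between the repeats.
    """
    seq = genome.sequence
    n = len(seq)
    k = min(seed_k, min_ir_len)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)

    raw: set[tuple[int, int, int, int]] = set()
    seen_pair: set[tuple[int, int]] = set()
    for i in range(n - k + 1):
        rc = reverse_complement(seq[i : i + k])
        for j in index.get(rc, ()):
            if j <= i:
                continue
            # left arm grows from [i, i+k), right arm from [j, j+k)
            a, b = i, j + k
            while a > 0 and b < n and seq[a - 1] == reverse_complement(seq[b]):
                a -= 1
                b += 1
            # extend right of seed / left of j
            c, d = i + k, j
            while c < n and d > 0 and c <= d - 1 and seq[c] == reverse_complement(seq[d - 1]):
                c += 1
                d -= 1
            L = c - a
            if L < min_ir_len:
                continue
            if d - c < min_insert:
                continue
            key = (a, c - 1, d, b - 1)
            if key in seen_pair:
                continue
            seen_pair.add((a, c - 1))
            raw.add(key)

    # tandem-periodic arms produce phase-shifted echoes of the same element;
    # any candidate whose arms overlap a longer kept candidate's arms is the
    # same element
    def _overlap(x0, x1, y0, y1):
        return x0 <= y1 and y0 <= x1

    merged: list[tuple[int, int, int, int]] = []
    for cand in sorted(raw, key=lambda t: (-(t[1] - t[0]), t[0])):
        dup = False
        for kept in merged:
            if _overlap(cand[0], cand[1], kept[0], kept[1]) and _overlap(
                cand[2], cand[3], kept[2], kept[3]
            ):
                dup = True
                break
        if not dup:
            merged.append(cand)

    elements = []
    for a, le, d, re_ in merged:
        insert_genes: tuple[str, ...] = ()
        if annotation is not None:
            genes = []
            for f in sorted(annotation.features, key=lambda f: f.start):
                if f.dna_region or _composite_or_antisense(f.name):
                    continue
                if f.end > le + 1 and f.start < d + 1 and not f.wraps_origin():
                    genes.append(f.name)
            insert_genes = tuple(genes)
        elements.append(
            TransposonLikeElement(
                left_start=a + 1,
                left_end=le + 1,
                right_start=d + 1,
                right_end=re_ + 1,
                insert_genes=insert_genes,
            )
        )
    elements.sort(key=lambda e: (e.left_start, e.right_start))
    return elements


def invert_element(genome: CircularGenome, element: TransposonLikeElement) -> CircularGenome:
    """Genome with the insert segment between the inverted repeats
    reverse-complemented (the 'inverted' configuration of the element)."""
    from dataclasses import replace

    s0 = element.insert_start - 1
    e0 = element.insert_end  # exclusive
    if e0 <= s0:
        raise ValueError("element has an empty insert")
    insert = genome.sequence[s0:e0]
    return replace(
        genome,
        sequence=genome.sequence[:s0] + reverse_complement(insert) + genome.sequence[e0:],
    )


def _mod_pos(pos: int, n: int) -> int:
    return (pos - 1) % n + 1


def _junction_strings(
    genome: CircularGenome, element: TransposonLikeElement, k: int
) -> tuple[list[str], list[str]]:
    """(reference, inverted) junction strings.

    When the repeat arms are exact reverse complements, the inverted element
    is locally the reverse complement of the reference element, so a string
    confined to one IR/insert boundary cannot tell the configurations apart
    (reads from the opposite strand of the other boundary mimic it). Each
    junction string therefore spans k bp of outer flank, the entire repeat
    arm and k bp of insert — reads must out-span the arms, which is exactly
    why long reads are needed when the arms approach the read length.
    """
    ref = genome
    inv = invert_element(genome, element)
    n = genome.length

    def junctions(g: CircularGenome) -> list[str]:
        left = g.fetch(
            _mod_pos(element.left_start - k, n), _mod_pos(element.left_end + k, n)
        )
        right = g.fetch(
            _mod_pos(element.right_start - k, n), _mod_pos(element.right_end + k, n)
        )
        return [left, right]

    return junctions(ref), junctions(inv)


def inversion_junction_support(
    reads: Iterable[str],
    element: TransposonLikeElement,
    genome: CircularGenome,
    k: int = 20,
) -> tuple[int, int]:
    """Count reads exactly containing the reference vs inverted junction
    sequences (either strand). Counts are evidence of each configuration,
    not a genotype call.

    Raises when the reads are too short to span a junction string
    (arm length + 2k).
    """
    ref_j, inv_j = _junction_strings(genome, element, k)
    # a junction string present in the other configuration is uninformative
    ref_keep = [
        s for s in ref_j if s not in inv_j and reverse_complement(s) not in inv_j
    ]
    inv_keep = [
        s for s in inv_j if s not in ref_j and reverse_complement(s) not in ref_j
    ]
    ref_j, inv_j = ref_keep, inv_keep
    junction_len = element.ir_length() + 2 * k
    ref_count = 0
    inv_count = 0
    checked = False
    for read in reads:
        if not checked:
            if len(read) < junction_len:
                raise ValueError(
                    f"reads shorter than a junction string "
                    f"(arm {element.ir_length()} bp + 2*k = {junction_len} bp)"
                )
            checked = True
        rc = reverse_complement(read)
        if any(j in read or j in rc for j in ref_j):
            ref_count += 1
        if any(j in read or j in rc for j in inv_j):
            inv_count += 1
    return ref_count, inv_count


def consensus_decomposition(
    decompositions: Sequence[ArrayDecomposition],
) -> ArrayDecomposition:
    """Modal decomposition over a read multiset — a stand-in for the Sanger
    consensus of heterogeneous arrays (majority pattern wins; ties broken by
    higher counted copy number, then pattern string)."""
    if not decompositions:
        raise ValueError("no decompositions to take a consensus of")
    from collections import Counter

    votes = Counter(d.pattern() for d in decompositions)
    best_pattern, _ = max(
        votes.items(), key=lambda kv: (kv[1], max(
            d.counted_copies() for d in decompositions if d.pattern() == kv[0]
        ), kv[0])
    )
    for d in decompositions:
        if d.pattern() == best_pattern:
            return d
    raise AssertionError("unreachable")
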