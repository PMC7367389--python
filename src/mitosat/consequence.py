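"""Coding consequence of STR copy-number changes inside protein-coding genes.

Translation uses NCBI genetic code table 5 (invertebrate mitochondrial):
TAA/TAG are stops, TGA is Trp, AGA/AGG are Ser, ATA is Met.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Data import CodonTable

from mitosat.genome_annotation import (
    AnnotationFeature,
    CircularGenome,
    reverse_complement,
)
from mitosat.str_catalog import STRLocus

__all__ = [
    "CodingConsequence",
    "apply_cnv",
    "translate_to_stop",
    "coding_consequence",
    "INVERTEBRATE_MITO_TABLE",
]

INVERTEBRATE_MITO_TABLE = 5

CLASS_SYNONYMOUS_LENGTH = "synonymous_length"
CLASS_IN_FRAME = "in_frame"
CLASS_FRAMESHIFT = "frameshift_truncation"
CLASS_STOP_LOSS = "stop_loss"


@dataclass(frozen=True)
class CodingConsequence:
    gene: str
    locus: STRLocus
    delta_copies: int
    consequence: str
    cds_bp_to_stop: int | None  # includes the stop codon; None on stop loss
    protein_aa: int | None  # excludes the stop codon
    protein: str = ""
    note: str = ""


def apply_cnv(
    genome: CircularGenome, locus: STRLocus, delta_copies: int
) -> CircularGenome:
    """Resize the STR array by ``delta_copies`` whole units; the genome
    length changes by ``delta_copies * unit_length``."""
    m, n = locus.unit_length, locus.copies
    if delta_copies < -(n - 1):
        raise ValueError(
            f"cannot delete {-delta_copies} units from an array of {n} copies"
        )
    start0 = locus.position - 1
    end0 = start0 + locus.array_length  # exclusive
    if end0 > genome.length:
        raise ValueError(
            f"STR array at {locus.position} extends past the linearized genome; "
            "rotate the origin before applying a CNV to a wrapping array"
        )
    observed = genome.sequence[start0:end0]
    if observed != locus.unit * n:
        raise ValueError(
            f"genome does not carry {locus.label()} at position {locus.position} "
            f"(found {observed!r})"
        )
    new_array = locus.unit * (n + delta_copies)
    return replace(
        genome, sequence=genome.sequence[:start0] + new_array + genome.sequence[end0:]
    )


def _code_tables(code: int):
    table = CodonTable.unambiguous_dna_by_id[code]
    return table.forward_table, set(table.stop_codons)


def translate_to_stop(cds: str, code: int = INVERTEBRATE_MITO_TABLE) -> tuple[int | None, int | None, str]:
    """Walk codons from the first base to the first stop codon.

    Returns ``(cds_bp_to_stop, protein_aa, protein)`` where the bp count
    includes the stop codon and the aa count excludes it. Both are ``None``
    when no stop occurs before the end of the sequence (stop loss /
    incomplete stop codon).
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if set(cds) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters")
    forward, stops = _code_tables(code)
    protein = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in stops:
            return i + 3, len(protein), "".join(protein)
        protein.append(forward[codon])
    return None, None, "".join(protein)


def _cds_window(genome: CircularGenome, gene: AnnotationFeature, max_bp: int) -> str:
    """Sequence downstream of the gene start on the coding strand, running up
    to ``max_bp`` around the circle (a frameshifted stop may lie past the
    annotated gene end)."""
    n = genome.length
    doubled = genome.sequence + genome.sequence
    if gene.strand == "+":
        start0 = gene.start - 1
        window = doubled[start0 : start0 + min(max_bp, n)]
        return window
    # minus-strand gene: coding sequence starts at the gene *end* coordinate
    # and runs leftwards; equivalently revcomp of the window ending at `end`
    end0 = gene.end  # exclusive on the plus strand
    length = min(max_bp, n)
    left = end0 - length
    if left >= 0:
        window = genome.sequence[left:end0]
    else:
        window = genome.sequence[left % n :] + genome.sequence[:end0]
    return reverse_complement(window)


def _locus_in_gene(locus: STRLocus, gene: AnnotationFeature, n: int) -> bool:
    if gene.wraps_origin():
        covered = locus.position >= gene.start or locus.position <= gene.end
    else:
        covered = gene.start <= locus.position <= gene.end
    return covered


def coding_consequence(
    genome: CircularGenome,
    gene: AnnotationFeature,
    locus: STRLocus,
    delta_copies: int,
    code: int = INVERTEBRATE_MITO_TABLE,
) -> CodingConsequence:
    """Consequence of a whole-unit CNV inside a protein-coding gene.

    A zero-length change is length-synonymous; a change that is a multiple
    of 3 stays in frame; otherwise the mutated CDS is translated from the
    gene start to the first stop, reporting the truncated protein.
    """
    if not _locus_in_gene(locus, gene, genome.length):
        raise ValueError(
            f"STR position {locus.position} lies outside gene {gene.name} "
            f"({gene.start}-{gene.end})"
        )
    delta_bases = delta_copies * locus.unit_length
    mutated = apply_cnv(genome, locus, delta_copies)
    if gene.strand == "-" and gene.end > locus.position:
        # insertion shifts downstream plus-strand coordinates; the minus
        # strand CDS ends at `end`, which moves with the indel
        gene = AnnotationFeature(
            name=gene.name,
            strand=gene.strand,
            start=gene.start,
            end=gene.end + delta_bases,
            dna_region=gene.dna_region,
        )
    window = _cds_window(mutated, gene, mutated.length)
    bp, aa, protein = translate_to_stop(window, code=code)

    if delta_copies == 0:
        cls = CLASS_SYNONYMOUS_LENGTH
    elif delta_bases % 3 == 0:
        cls = CLASS_IN_FRAME
    elif bp is None:
        cls = CLASS_STOP_LOSS
    else:
        cls = CLASS_FRAMESHIFT
    note = ""
    if bp is None:
        note = (
            "no stop codon before the end of the scanned window; possibly an "
            "incomplete (polyadenylation-completed) stop"
        )
    return CodingConsequence(
        gene=gene.name,
        locus=locus,
        delta_copies=delta_copies,
        consequence=cls,
        cds_bp_to_stop=bp,
        protein_aa=aa,
        protein=protein,
        note=note,
    )
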