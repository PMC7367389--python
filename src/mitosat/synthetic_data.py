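"""Ground-truth simulation: genomes with planted repeats, slippage-driven
allele distributions, deep pileup columns and read sets.

The copy-number mutation process is a lazy reflecting random walk: each of
``g`` propagation events leaves the copy number unchanged with probability
1 - 2p and moves it by +/-1 with probability p each, reflecting at one
copy. That minimal mechanism reproduces the +/-1-dominant allele tables the
analysis expects at deep coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from mitosat.genome_annotation import CircularGenome, reverse_complement
from mitosat.pileup_io import PileupColumn, write_pileup
from mitosat.repeat_architecture import TransposonLikeElement, invert_element
from mitosat.str_catalog import STRLocus
from collections import Counter

__all__ = [
    "SlippageModel",
    "GenomeConfig",
    "IRElementSpec",
    "PlantedSNP",
    "SyntheticTruth",
    "generate_genome",
    "slippage_distribution",
    "simulate_pileup",
    "simulate_reads",
    "write_truth_tsv",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SlippageModel:
    """Per-event slippage probability ``p``, number of propagation events
    ``g`` and substitution error rate ``e``."""

    p: float = 0.005
    g: int = 4
    e: float = 0.0
    max_copy_change: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 0.5):
            raise ValueError("slippage probability p must lie in [0, 0.5]")
        if not (0.0 <= self.e <= 1.0):
            raise ValueError("substitution rate e must lie in [0, 1]")
        if self.g < 0:
            raise ValueError("event count g must be >= 0")
        if self.max_copy_change != 1:
            raise ValueError("only single-unit slippage steps are supported")


@dataclass(frozen=True)
class IRElementSpec:
    """A planted inverted-repeat element: ``copies`` repeats of a random
    ``unit_len``-bp unit on the left, an ``insert_len``-bp insert, and the
    reverse-complementary array on the right."""

    unit_len: int = 34
    copies: int = 5
    insert_len: int = 600


@dataclass(frozen=True)
class PlantedSNP:
    position: int  # filled in during generation when 0
    base: str
    frequency: float


@dataclass(frozen=True)
class GenomeConfig:
    length: int = 15000
    at_fraction: float = 0.78
    strs: tuple[tuple[str, int], ...] = (
        ("G", 8),
        ("A", 9),
        ("TA", 9),
        ("T", 10),
        ("A", 12),
    )
    ir_element: IRElementSpec | None = IRElementSpec()
    snps: tuple[PlantedSNP, ...] = ()
    genome_id: str = "synthetic_mt"


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for use as a test oracle."""

    genome: CircularGenome
    loci: list[STRLocus] = field(default_factory=list)
    allele_frequencies: dict[int, dict[int, float]] = field(default_factory=dict)
    # position -> {delta copies -> frequency}; delta 0 is the reference
    element: TransposonLikeElement | None = None
    element_unit: str = ""
    snps: list[PlantedSNP] = field(default_factory=list)


def _random_background(rng: np.random.Generator, length: int, at_fraction: float) -> list[str]:
    at = at_fraction / 2.0
    gc = (1.0 - at_fraction) / 2.0
    return list(rng.choice(list("ATCG"), size=length, p=[at, at, gc, gc]))


def _pick_base(rng: np.random.Generator, exclude: set[str]) -> str:
    choices = [b for b in _BASES if b not in exclude]
    return choices[rng.integers(len(choices))]


def slippage_distribution(n0: int, model: SlippageModel) -> dict[int, float]:
    """Exact copy-number distribution after ``g`` lazy reflecting walk
    events starting from ``n0`` copies (support truncated at probability
    mass 0)."""
    if n0 < 2:
        raise ValueError("reference copy number must be >= 2")
    size = n0 + model.g + 1  # states 1 .. n0+g, index 0 unused
    probs = np.zeros(size + 1)
    probs[n0] = 1.0
    p = model.p
    for _ in range(model.g):
        nxt = np.zeros_like(probs)
        nxt += probs * (1.0 - 2.0 * p)
        nxt[2:] += probs[1:-1] * p  # up moves
        nxt[1:-1] += probs[2:] * p  # down moves
        nxt[1] += probs[1] * p  # reflection: a down move at 1 stays
        probs = nxt
    out = {}
    for copies in range(1, size + 1):
        if copies <= size and probs[copies] > 0.0:
            out[copies] = float(probs[copies])
    return out


def _frequency_by_delta(locus: STRLocus, model: SlippageModel) -> dict[int, float]:
    dist = slippage_distribution(locus.copies, model)
    return {copies - locus.copies: freq for copies, freq in dist.items()}


def generate_genome(
    config: GenomeConfig, seed: int, model: SlippageModel | None = None
) -> tuple[CircularGenome, SyntheticTruth]:
    """Build a circular genome carrying the configured STRs and IR element
    at recorded coordinates, deterministic under ``seed``.

    Planted repeats get maximality-preserving flanks so the scanner
    recovers them at exactly the planted positions.
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = SlippageModel()

    pieces: list[tuple[str, object]] = [("str", (u, c)) for u, c in config.strs]
    if config.ir_element is not None:
        pieces.append(("element", config.ir_element))
    # +1 bp per STR for the dedicated right-flank base
    planted_len = sum(len(u) * c + 1 for u, c in config.strs)
    if config.ir_element is not None:
        spec = config.ir_element
        planted_len += 2 * spec.unit_len * spec.copies + spec.insert_len
    n_gaps = len(pieces) + 1
    slack = config.length - planted_len
    if slack < 2 * n_gaps:
        raise ValueError(
            f"planted features ({planted_len} bp) do not fit a {config.length} bp genome"
        )
    gap = slack // n_gaps
    gaps = [gap] * n_gaps
    gaps[-1] += slack - gap * n_gaps

    seq: list[str] = []
    truth = SyntheticTruth(genome=None)  # genome filled at the end
    for piece_idx, (kind, payload) in enumerate(pieces):
        seq.extend(_random_background(rng, gaps[piece_idx], config.at_fraction))
        if kind == "str":
            unit, copies = payload
            # flanks must not extend the array: left flank != last unit base,
            # right flank is fixed after appending the array
            if seq and seq[-1] == unit[-1]:
                seq[-1] = _pick_base(rng, {unit[-1]})
            position = len(seq) + 1
            seq.extend(unit * copies)
            locus = STRLocus(position=position, unit=unit, copies=copies)
            truth.loci.append(locus)
            truth.allele_frequencies[position] = _frequency_by_delta(locus, model)
            seq.append(_pick_base(rng, {unit[0]}))
        else:
            spec = payload
            unit = "".join(
                _random_background(rng, spec.unit_len, 0.5)
            )  # GC-balanced: keeps arms unique in an AT-rich background
            left = unit * spec.copies
            right = reverse_complement(left)
            if seq and seq[-1] == left[-1]:
                seq[-1] = _pick_base(rng, {left[-1]})
            left_start = len(seq) + 1
            seq.extend(left)
            insert = _random_background(rng, spec.insert_len, config.at_fraction)
            # the insert edges must not pair, or arm extension swallows them
            while insert[0] == reverse_complement(insert[-1]):
                insert[0] = _pick_base(rng, {insert[0]})
            seq.extend(insert)
            right_start = len(seq) + 1
            seq.extend(right)
            truth.element = TransposonLikeElement(
                left_start=left_start,
                left_end=left_start + len(left) - 1,
                right_start=right_start,
                right_end=right_start + len(right) - 1,
            )
            truth.element_unit = unit
    seq.extend(_random_background(rng, gaps[-1], config.at_fraction))
    # outer flanks of the element must not pair either
    if truth.element is not None:
        el = truth.element
        if el.left_start > 1 and el.right_end < len(seq):
            before = seq[el.left_start - 2]
            after_idx = el.right_end  # 0-based position just right of the arm
            if seq[after_idx] == reverse_complement(before):
                seq[after_idx] = _pick_base(rng, {seq[after_idx]})

    genome = CircularGenome(id=config.genome_id, sequence="".join(seq))
    truth.genome = genome

    snps = []
    for snp in config.snps:
        pos = snp.position
        if pos == 0:
            # drop it on background, away from planted features
            pos = int(rng.integers(1, genome.length + 1))
            while any(
                l.position <= pos <= l.end for l in truth.loci
            ) or (
                truth.element is not None
                and truth.element.left_start <= pos <= truth.element.right_end
            ):
                pos = int(rng.integers(1, genome.length + 1))
        base = snp.base or _pick_base(rng, {genome.base_at(pos)})
        if base == genome.base_at(pos):
            base = _pick_base(rng, {genome.base_at(pos)})
        snps.append(PlantedSNP(position=pos, base=base, frequency=snp.frequency))
    truth.snps = snps
    return genome, truth


def _allele_label(locus: STRLocus, delta: int) -> str:
    if delta == 0:
        return "Ref"
    seq = locus.unit * abs(delta)
    sign = "+" if delta > 0 else "-"
    return f"{sign}{len(seq)}{seq}"


def simulate_pileup(
    truth: SyntheticTruth,
    depth: int,
    model: SlippageModel,
    seed: int,
    positions: Sequence[int] | None = None,
) -> list[PileupColumn]:
    """Draw allele counts at each requested position (default: the planted
    STR anchors plus planted SNP sites).

    STR anchors draw multinomially from the locus's truth frequencies;
    other positions draw substitution noise at rate ``e`` (and the planted
    SNP frequency at SNP sites).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    genome = truth.genome
    by_anchor = {l.position: l for l in truth.loci}
    snp_by_pos = {s.position: s for s in truth.snps}
    if positions is None:
        positions = sorted(set(by_anchor) | set(snp_by_pos))

    columns = []
    for pos in positions:
        ref_base = genome.base_at(pos)
        counts: Counter = Counter()
        if pos in by_anchor:
            locus = by_anchor[pos]
            freqs = truth.allele_frequencies[locus.position]
            deltas = sorted(freqs)
            pvals = np.array([freqs[d] for d in deltas], dtype=float)
            pvals = pvals / pvals.sum()
            draws = rng.multinomial(depth, pvals)
            for delta, count in zip(deltas, draws):
                if count:
                    counts[_allele_label(locus, delta)] += int(count)
        else:
            n_err = rng.binomial(depth, model.e) if model.e > 0 else 0
            snp = snp_by_pos.get(pos)
            n_snp = rng.binomial(depth - n_err, snp.frequency) if snp else 0
            for _ in range(int(n_err)):
                counts[_pick_base(rng, {ref_base})] += 1
            if n_snp:
                counts[snp.base] += int(n_snp)
            counts["Ref"] += depth - int(n_err) - int(n_snp)
        columns.append(
            PileupColumn(
                chrom=genome.id,
                position=pos,
                ref_base=ref_base,
                depth=depth,
                counts=counts,
            )
        )
    return columns


def simulate_pileup_file(
    truth: SyntheticTruth,
    depth: int,
    model: SlippageModel,
    seed: int,
    path: str | Path,
    positions: Sequence[int] | None = None,
) -> None:
    write_pileup(simulate_pileup(truth, depth, model, seed, positions), path)


def simulate_reads(
    truth: SyntheticTruth,
    read_len: int,
    depth: float,
    inversion_fraction: float = 0.0,
    seed: int = 0,
) -> Iterator[tuple[str, str]]:
    """Yield ``(name, sequence)`` reads sampled uniformly around the circle,
    random strand; a fraction of molecules carry the inverted element."""
    genome = truth.genome
    n = genome.length
    if read_len >= n:
        raise ValueError("read length must be shorter than the genome")
    if not 0.0 <= inversion_fraction <= 1.0:
        raise ValueError("inversion fraction must lie in [0, 1]")
    if inversion_fraction > 0.0 and truth.element is None:
        raise ValueError("no planted element to invert")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * n / read_len))
    doubled_ref = genome.sequence + genome.sequence
    doubled_inv = None
    if truth.element is not None:
        inv = invert_element(genome, truth.element)
        doubled_inv = inv.sequence + inv.sequence

    starts = rng.integers(0, n, size=n_reads)
    inverted = (
        rng.random(n_reads) < inversion_fraction
        if inversion_fraction > 0.0
        else np.zeros(n_reads, dtype=bool)
    )
    flip = rng.random(n_reads) < 0.5
    for i in range(n_reads):
        src = doubled_inv if inverted[i] else doubled_ref
        s = int(starts[i])
        read = src[s : s + read_len]
        if flip[i]:
            read = reverse_complement(read)
        tag = "inv" if inverted[i] else "ref"
        yield f"read_{i}_{tag}_{s + 1}_{'-' if flip[i] else '+'}", read


def write_reads_fasta(
    reads: Iterator[tuple[str, str]], path: str | Path
) -> int:
    count = 0
    with Path(path).open("w") as fh:
        for name, seq in reads:
            fh.write(f">{name}\n{seq}\n")
            count += 1
    return count


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    """Planted loci and their allele frequencies, one allele per row."""
    with Path(path).open("w") as fh:
        fh.write("Position\tUnit\tCopies\tDelta\tFrequency\n")
        for locus in truth.loci:
            for delta, freq in sorted(truth.allele_frequencies[locus.position].items()):
                fh.write(
                    f"{locus.position}\t{locus.unit}\t{locus.copies}\t{delta}\t{freq:.10g}\n"
                )
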