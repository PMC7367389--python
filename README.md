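# mitosat

STR copy-number variation analysis for circular mitochondrial genomes.

`mitosat` implements, as a tested and reusable pipeline, the analysis of
short-tandem-repeat (STR) copy-number heteroplasmy in small circular
genomes sequenced to very deep coverage:

- **`genome_annotation`** — circular-genome data model with 1-based
  wrap-around coordinates, precise-annotation TSV I/O, strand-coverage
  validation (gap/overlap report) and GFF3 export.
- **`str_catalog`** — maximal primitive-unit STR scanning (`[unit]n`
  notation, "m x n" classification), including runs crossing the origin of
  a circular sequence.
- **`pileup_io`** — a samtools-style pileup dialect in which every
  insertion/deletion label is one observation (depths correspond one-to-one
  with allele labels), plus expansion of indel alleles into concrete STR
  copy numbers.
- **`cnv_calling`** — per-locus allele tables (reference = most frequent
  allele), the alternative-allele ratio, the >1% selection rule, allele
  classification (whole-unit CNV / substitution / other) and an SNP scan.
- **`consequence`** — applying a copy-number change to the genome and
  predicting frameshift truncations under the invertebrate mitochondrial
  genetic code (NCBI table 5).
- **`repeat_architecture`** — decomposition of long tandem arrays into
  named unit types (hybrid arrays, partial trailing units),
  reverse-complement unit matching, inverted-repeat element detection and
  read-level inversion-junction support counting.
- **`synthetic_data`** — ground-truth simulation: genomes with planted
  STRs/inverted-repeat elements, an exact replication-slippage copy-number
  distribution (lazy reflecting random walk), deep pileup columns and read
  sets with a configurable inverted-molecule fraction.
- **`cli_pipeline`** — the `mitosat` command line.

Two reference tables are packaged (`mitosat/data/`): a precise annotation
of a 15,094-bp tick mt genome whose features tile both strands without
gaps or overlaps, and a 20-position STR allele/depth table used throughout
the tests.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion. The
accession-dependent criterion (translating the real reference genome)
requires a genome FASTA at `data/MN347015.fasta` (or the
`MITOSAT_REFERENCE_FASTA` environment variable); without it that single
test fails with an explanatory message — everything else runs offline.

## CLI

```sh
mitosat validate-annotation                  # packaged table: gap/overlap check
mitosat call --fixture --out calls.tsv       # allele ratios + 1% selection
mitosat simulate --seed 7 --out sim/         # synthetic genome/pileup/truth
mitosat scan --genome sim/genome.fasta --out catalog.tsv
mitosat call --pileup sim/strs.pileup --catalog sim/catalog.tsv --out calls.tsv
mitosat repeats --genome sim/genome.fasta --out elements.tsv
mitosat consequence --genome sim/genome.fasta --annotation ann.tsv \
    --gene COI --position 1810 --unit G --copies 8 --delta 1
mitosat fixtures --out fixtures/             # write the packaged tables
```

Every output TSV begins with a comment recording the tool version, a
config hash and the seed. Simulations refuse to run without an explicit
seed.

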