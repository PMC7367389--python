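"""Accessors for the packaged reference tables (tick mt genome annotation
and the 20-position STR allele-depth table)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from mitosat.genome_annotation import AnnotationSet, load_annotation_table
from mitosat.pileup_io import AlleleFixtureRow, read_allele_fixture

ANNOTATION_FILENAME = "dsilvarum_annotation.tsv"
ALLELES_FILENAME = "dsilvarum_str_alleles.tsv"


def _data_path(name: str) -> Path:
    return Path(resources.files("mitosat").joinpath("data", name))


def annotation_path() -> Path:
    return _data_path(ANNOTATION_FILENAME)


def alleles_path() -> Path:
    return _data_path(ALLELES_FILENAME)


def load_annotation() -> AnnotationSet:
    """The packaged precise annotation (both strands tile a 15,094-bp circle)."""
    return load_annotation_table(annotation_path())


def load_str_alleles() -> list[AlleleFixtureRow]:
    """The packaged 20-position allele/depth table."""
    return read_allele_fixture(alleles_path())
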