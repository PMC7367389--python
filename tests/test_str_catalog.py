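import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitosat.str_catalog import (
    STRLocus,
    canonical_unit,
    classify_str,
    find_strs,
    format_str,
    locus_on_reverse_complement,
    parse_str,
    read_catalog,
    write_catalog,
)
from mitosat.genome_annotation import reverse_complement


def _is_primitive(unit):
    m = len(unit)
    return not any(m % d == 0 and unit[:d] * (m // d) == unit for d in range(1, m))


def brute_force_strs(seq, max_unit=6, min_copies=None, min_array_len=8):
    """Independent oracle: enumerate every (start, unit length), greedily
    extend, keep base-level-maximal primitive runs."""
    if min_copies is None:
        min_copies = {1: 5}
    n = len(seq)
    out = []
    for m in range(1, max_unit + 1):
        for s in range(n - 2 * m + 1):
            unit = seq[s : s + m]
            if not _is_primitive(unit):
                continue
            k = 1
            while seq[s + k * m : s + (k + 1) * m] == unit:
                k += 1
            if k < 2:
                continue
            if s > 0 and seq[s - 1] == seq[s - 1 + m]:
                continue  # extends left: not the anchor
            threshold = min_copies.get(m, 3 if m > 1 else 5)
            if k < threshold:
                continue
            if m >= 2 and m * k < min_array_len:
                continue
            out.append((s + 1, unit, k))
    return sorted(out)


def as_tuples(loci):
    return sorted((l.position, l.unit, l.copies) for l in loci)


class TestNotation:
    def test_format(self):
        assert format_str("AT", 5) == "[AT]5"

    def test_parse_plain_and_underscored(self):
        assert parse_str("[G]8") == ("G", 8)
        assert parse_str("[AT]_5_") == ("AT", 5)

    def test_parse_empty_unit_fails(self):
        with pytest.raises(ValueError):
            parse_str("[]3")

    @given(
        unit=st.text(alphabet="ACGT", min_size=1, max_size=6),
        copies=st.integers(2, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, unit, copies):
        assert parse_str(format_str(unit, copies)) == (unit, copies)

    def test_classify(self):
        assert classify_str(STRLocus(1, "AT", 5)) == "2 x 5"
        assert classify_str(STRLocus(1, "G", 8)) == "1 x 8"
        assert classify_str(STRLocus(1, "TTAGGG", 4)) == "6 x 4"


class TestSTRLocus:
    def test_rejects_non_primitive_unit(self):
        with pytest.raises(ValueError):
            STRLocus(1, "ATAT", 3)

    def test_array_length(self):
        assert STRLocus(10, "TA", 9).array_length == 18
        assert STRLocus(10, "TA", 9).end == 27

    def test_canonical_unit(self):
        assert canonical_unit("TA") == "AT"
        assert canonical_unit("GCA") == "AGC"


class TestFindStrs:
    def test_dinucleotide_example(self):
        loci = find_strs("ATATATATAT", min_array_len=8)
        assert as_tuples(loci) == [(1, "AT", 5)]

    def test_homopolymer_prefers_single_base_unit(self):
        loci = find_strs("AAAAAAAA")
        assert as_tuples(loci) == [(1, "A", 8)]

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            find_strs("")

    def test_thresholds(self):
        assert find_strs("AAAA") == []  # 4 < 5 copies for unit length 1
        assert as_tuples(find_strs("AAAA", min_copies_by_unit_len={1: 4})) == [
            (1, "A", 4)
        ]

    def test_matches_brute_force_on_random_40mers(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            assert as_tuples(find_strs(seq)) == brute_force_strs(seq)

    def test_matches_brute_force_on_at_rich_40mers(self, rng):
        for _ in range(200):
            seq = "".join(
                rng.choice(list("ATCG"), size=40, p=[0.39, 0.39, 0.11, 0.11])
            )
            permissive = {m: 2 for m in range(1, 7)}
            assert as_tuples(
                find_strs(seq, min_copies_by_unit_len=permissive, min_array_len=2)
            ) == brute_force_strs(seq, min_copies=permissive, min_array_len=2)

    @given(seq=st.text(alphabet="AT", min_size=10, max_size=50))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_two_letter_alphabet(self, seq):
        permissive = {m: 2 for m in range(1, 7)}
        assert as_tuples(
            find_strs(seq, min_copies_by_unit_len=permissive, min_array_len=2)
        ) == brute_force_strs(seq, min_copies=permissive, min_array_len=2)

    def test_circular_wrap_reported_once(self):
        # [A]5 wrapping the origin: 2 leading + 3 trailing
        seq = "AATTCGGCTTCAAA"
        loci = find_strs(seq, circular=True)
        assert as_tuples(loci) == [(12, "A", 5)]
        assert find_strs(seq, circular=False) == []

    def test_circular_full_homopolymer(self):
        loci = find_strs("AAAAAA", circular=True)
        assert as_tuples(loci) == [(1, "A", 6)]

    def test_maximality_on_random_strings(self, rng):
        permissive = {m: 2 for m in range(1, 7)}
        for _ in range(50):
            seq = "".join(rng.choice(list("AT"), size=30))
            for locus in find_strs(
                seq, min_copies_by_unit_len=permissive, min_array_len=2
            ):
                s0 = locus.position - 1
                m = locus.unit_length
                assert seq[s0 : s0 + locus.array_length] == locus.unit * locus.copies
                if s0 > 0:
                    assert seq[s0 - 1] != seq[s0 - 1 + m]
                nxt = s0 + locus.copies * m
                if nxt + m <= len(seq):
                    assert seq[nxt : nxt + m] != locus.unit

    def test_no_same_unit_overlaps(self, rng):
        permissive = {m: 2 for m in range(1, 7)}
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            loci = find_strs(seq, min_copies_by_unit_len=permissive, min_array_len=2)
            by_unit = {}
            for l in loci:
                by_unit.setdefault(canonical_unit(l.unit), []).append(l)
            for group in by_unit.values():
                group.sort(key=lambda l: l.position)
                for a, b in zip(group, group[1:]):
                    assert a.end < b.position

    def test_reverse_complement_symmetry(self, rng):
        permissive = {m: 2 for m in range(1, 7)}
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            fwd = find_strs(seq, min_copies_by_unit_len=permissive, min_array_len=2)
            rev = find_strs(
                reverse_complement(seq),
                min_copies_by_unit_len=permissive,
                min_array_len=2,
            )
            assert len(fwd) == len(rev)
            mirrored = [locus_on_reverse_complement(l, len(seq)) for l in fwd]
            unmatched = list(rev)
            for mir in mirrored:
                m = mir.unit_length
                hit = next(
                    (
                        g
                        for g in unmatched
                        if g.copies == mir.copies
                        and canonical_unit(g.unit) == canonical_unit(mir.unit)
                        # anchor may shift by a partial-unit phase
                        and abs(g.position - mir.position) < m
                    ),
                    None,
                )
                assert hit is not None, (mir, unmatched)
                unmatched.remove(hit)
            assert unmatched == []


class TestCatalogIO:
    def test_round_trip(self, tmp_path, annotation):
        loci = [STRLocus(1810, "G", 8), STRLocus(7324, "TA", 9)]
        p = tmp_path / "cat.tsv"
        write_catalog(loci, p, annotation=annotation, header_comment="v test")
        text = p.read_text()
        assert "COI" in text and "16S rRNA" in text
        assert read_catalog(p) == loci
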