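"""Bit-exact component codecs and whole-document TRZ I/O."""

import itertools
import random
from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st

from treezip import TRZDocument, TRZError, TRZHeader, TRZLine, read_trz, write_trz
from treezip.bipartitions import text_to_mask
from treezip.trees import TaxaIndex
from treezip.trz_codec import (
    decode_bitstring_rle,
    decode_id_list,
    decode_weights,
    encode_bitstring_rle,
    encode_id_list,
    encode_weights,
)


class TestBitstringRLE:
    @pytest.mark.parametrize(
        "text,expected",
        [("110000", "K2L4"), ("111111", "K6"), ("000111", "L3K3"), ("1", "K1"),
         ("101010", "K1L1K1L1K1L1")],
    )
    def test_examples(self, text, expected):
        n = len(text)
        assert encode_bitstring_rle(text_to_mask(text), n) == expected
        assert decode_bitstring_rle(expected, n) == text_to_mask(text)

    def test_exhaustive_roundtrip_small_n(self):
        for n in range(1, 11):
            for mask in range(1 << n):
                assert decode_bitstring_rle(encode_bitstring_rle(mask, n), n) == mask

    @pytest.mark.parametrize("bad", ["K2L3", "K7", "2K4", "K2K4", "K0L6", "", "K2L4X"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(TRZError):
            decode_bitstring_rle(bad, 6)


class TestIdListCodec:
    def test_complement_singleton_encodes_as_C(self):
        assert encode_id_list([0, 1], 3) == ("-", "C")
        assert decode_id_list("-", "C", 3) == (0, 1)

    def test_full_membership_is_empty_minus_payload(self):
        assert encode_id_list(list(range(4)), 4) == ("-", "")
        assert decode_id_list("-", "", 4) == (0, 1, 2, 3)

    def test_run_length_marker(self):
        assert encode_id_list([1, 3, 5, 7], 10) == ("+", "BCM3")
        assert decode_id_list("+", "BCM3", 10) == (1, 3, 5, 7)

    def test_multi_digit_deltas(self):
        members = [0, 123, 246]
        sign, payload = encode_id_list(members, 1000)
        assert sign == "+" and payload == "AB23M2"
        assert decode_id_list(sign, payload, 1000) == tuple(members)

    def test_tie_prefers_members(self):
        sign, _ = encode_id_list([0, 1], 4)
        assert sign == "+"

    def test_exhaustive_roundtrip_small_universes(self):
        for u in range(1, 13):
            for r in range(1, u + 1):
                for members in itertools.combinations(range(u), r):
                    sign, payload = encode_id_list(members, u)
                    assert decode_id_list(sign, payload, u) == members
                    # the listed set is never larger than its complement
                    listed = members if sign == "+" else tuple(
                        i for i in range(u) if i not in members
                    )
                    assert len(listed) <= u - len(listed) or sign == "+"

    @given(st.integers(20, 2000).flatmap(
        lambda u: st.tuples(st.just(u), st.sets(st.integers(0, u - 1), min_size=1))))
    @settings(max_examples=200, derandomize=True)
    def test_random_roundtrip(self, case):
        u, member_set = case
        members = tuple(sorted(member_set))
        sign, payload = encode_id_list(members, u)
        assert decode_id_list(sign, payload, u) == members

    @pytest.mark.parametrize("sign,payload", [("+", "M3"), ("+", "3B"), ("+", "BM0"),
                                              ("+", "BMB"), ("x", "B")])
    def test_malformed_rejected(self, sign, payload):
        with pytest.raises(TRZError):
            decode_id_list(sign, payload, 10)

    def test_decoded_ids_must_fit_universe(self):
        with pytest.raises(TRZError):
            decode_id_list("+", "J", 5)  # id 9 in a universe of 5

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError):
            encode_id_list([0, 7], 5)


class TestWeightCodec:
    def test_pair_99_maps_to_byte_132(self):
        payload, exceptions = encode_weights([Decimal("0.99")], 6)
        assert payload == bytes([132, 33, 33])
        assert exceptions == ()

    def test_paper_style_mantissa(self):
        payload, exceptions = encode_weights([Decimal("0.32")], 6)
        assert payload == bytes([65, 33, 33])
        assert decode_weights(payload, exceptions, 1, 6) == (Decimal("0.320000"),)

    def test_integral_exception(self):
        payload, exceptions = encode_weights([Decimal("1.5")], 6)
        assert payload == bytes([50 + 33, 33, 33])
        assert exceptions == ((0, 1),)
        assert decode_weights(payload, exceptions, 1, 6) == (Decimal("1.500000"),)

    def test_rounding_half_away_from_zero(self):
        payload, _ = encode_weights([Decimal("0.0000005")], 6)
        assert decode_weights(payload, (), 1, 6) == (Decimal("0.000001"),)

    def test_random_roundtrip_at_mantissa_precision(self):
        rng = random.Random(123)
        lengths = [
            Decimal(rng.randrange(0, 10_000_000)).scaleb(-6) for _ in range(10_000)
        ]
        payload, exceptions = encode_weights(lengths, 6)
        assert decode_weights(payload, exceptions, len(lengths), 6) == tuple(lengths)

    def test_errors(self):
        with pytest.raises(ValueError):
            encode_weights([Decimal("-0.1")], 6)
        with pytest.raises(ValueError):
            encode_weights([Decimal("0.1")], 5)
        with pytest.raises(TRZError):
            decode_weights(b"!!", (), 1, 6)  # wrong payload length
        with pytest.raises(TRZError):
            decode_weights(bytes([200, 33, 33]), (), 1, 6)  # byte out of range


def _doc_from(taxa_names, rows, weighted, duplicates=None, t=None):
    """Assemble a document from (mask, members, weights) triples."""
    taxa = TaxaIndex(tuple(taxa_names))
    lines = [
        TRZLine(mask=m, members=tuple(mem), weights=tuple(w) if weighted else None)
        for m, mem, w in rows
    ]
    u = 1 + max(x for _, mem, _ in rows for x in mem)
    header = TRZHeader(
        taxa=taxa, t=t if t is not None else u, u=u,
        n_bipartitions=len(lines), weighted=weighted,
    )
    return TRZDocument(header=header, lines=lines, duplicates=duplicates or {})


class TestDocumentIO:
    def test_file1_document_shape(self, doc1):
        assert doc1.header.t == doc1.header.u == 3
        assert doc1.header.n_bipartitions == len(doc1.lines) == 15
        assert doc1.duplicates == {}
        blob = write_trz(doc1)
        head = blob.split(b"\n")[:4]
        assert head == [b"A B C D E F", b"3", b"15", b"U 3 W 1 K 6"]

    def test_write_read_write_is_byte_stable(self, doc1, doc2):
        for doc in (doc1, doc2):
            blob = write_trz(doc)
            assert write_trz(read_trz(blob)) == blob

    def test_line_permutation_writes_identical_bytes(self, doc1):
        rng = random.Random(0)
        for _ in range(5):
            lines = list(doc1.lines)
            rng.shuffle(lines)
            shuffled = TRZDocument(
                header=doc1.header, lines=lines, duplicates=dict(doc1.duplicates)
            )
            assert write_trz(shuffled) == write_trz(doc1)

    def test_duplicates_line_for_identical_trees(self):
        rows = [(0b100, [0], ["0.1"]), (0b010, [0], ["0.2"]), (0b001, [0], ["0.3"]),
                (0b110, [0], ["0.4"])]
        rows = [(m, mem, [Decimal(x) for x in w]) for m, mem, w in rows]
        doc = _doc_from("abc", rows, True, duplicates={0: (0, 1, 2, 3)}, t=4)
        blob = write_trz(doc)
        assert b"\nD 0 -\n" in blob  # every position belongs to unique tree 0
        assert read_trz(blob).duplicates == {0: (0, 1, 2, 3)}

    def test_out_of_order_lines_rejected(self, doc1):
        blob = write_trz(doc1)
        lines = blob.split(b"\n")
        lines[4], lines[5] = lines[5], lines[4]
        with pytest.raises(TRZError, match="order"):
            read_trz(b"\n".join(lines))

    def test_header_mismatch_rejected(self, doc1):
        blob = write_trz(doc1)
        lines = blob.split(b"\n")
        lines[2] = b"14"
        with pytest.raises(TRZError):
            read_trz(b"\n".join(lines))

    def test_unknown_section_tag_rejected(self, doc1):
        blob = write_trz(doc1) + b"X stray\n"
        with pytest.raises(TRZError, match="section"):
            read_trz(blob)

    def test_duplicate_coverage_violation_rejected(self):
        rows = [(0b100, [0], None), (0b010, [0], None), (0b001, [0], None)]
        rows = [(m, mem, []) for m, mem, _ in rows]
        with pytest.raises(TRZError, match="coverage|duplicate"):
            _doc_from("abc", rows, False, duplicates={}, t=3)  # t=3 but u=1, no D line

    def test_weight_bytes_are_length_delimited(self):
        # a weight byte equal to '!' (33) must not be mistaken for the
        # integral-exception marker
        rows = [(0b100, [0], [Decimal("0")]), (0b010, [0], [Decimal("0")]),
                (0b001, [0], [Decimal("1.0")])]
        doc = _doc_from("abc", rows, True)
        again = read_trz(write_trz(doc))
        line = [ln for ln in again.lines if ln.mask == 0b001][0]
        assert line.weights == (Decimal("1.000000"),)
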