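"""Encoders, decoders and file I/O for the TRZ compressed format.

TRZ is a plain-text (8-bit) semantic compression of a Newick tree
collection: each distinct bipartition of the collection is stored once,
with the set of unique trees that contain it and their branch lengths.

Dialect v1 layout (LF line endings):

* line 1 — taxon names, space-separated, lexicographic;
* line 2 — ``t``, the number of trees;
* line 3 — ``B``, the number of unique bipartitions;
* line 4 — ``U <u> W <0|1> K <mantissa_digits>`` (unique-tree count,
  weighted flag, branch-length precision);
* ``B`` bipartition lines, in canonical order (decreasing set-bit count,
  ties by decreasing bitstring text)::

      <RLE bitstring> <sign><id payload>[ <weight bytes>][ !<idx>:<int>[,...]]

* zero or more duplicate lines ``D <uid> <sign><positions payload>``.

Component codecs:

* bitstrings are run-length encoded, ``K<len>`` for runs of 1s and
  ``L<len>`` for runs of 0s (``110000`` -> ``K2L4``);
* a bipartition's tree-id set Γ or its complement Γ̄ — whichever is
  smaller — is stored (sign ``+``/``-``), as successive differences whose
  first digit is written A–J (0–9) with an ``M<count>`` marker for
  repeated differences;
* branch lengths are split into integral and mantissa; the mantissa's
  digit pairs map to single bytes via a +33 offset (``99`` -> byte 132),
  non-zero integrals are stored as explicit ``!index:value`` exceptions.

Weight payloads may contain any byte in 33..132, so they are length
delimited (exactly ``|Γ| * mantissa_digits/2`` bytes), never scanned for
sentinels.  The dialect claims no byte compatibility with other tools'
TRZ files.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional, Sequence

from .bipartitions import canonical_sort_key, mask_to_text, text_to_mask
from .trees import TaxaIndex, quantize_length

__all__ = [
    "TRZError",
    "TRZHeader",
    "TRZLine",
    "TRZDocument",
    "encode_bitstring_rle",
    "decode_bitstring_rle",
    "encode_id_list",
    "decode_id_list",
    "encode_weights",
    "decode_weights",
    "write_trz",
    "read_trz",
]

_DIGIT_TO_CHAR = "ABCDEFGHIJ"  # first digit 0..9 of each id delta
_CHAR_TO_DIGIT = {c: str(i) for i, c in enumerate(_DIGIT_TO_CHAR)}

#: weight bytes are two-digit groups 0..99 offset by 33 (printable range)
_WEIGHT_OFFSET = 33
_MAX_INTEGRAL = 10**9


class TRZError(ValueError):
    """Malformed TRZ data or an invalid document."""


# ---------------------------------------------------------------------------
# bitstring run-length codec


def encode_bitstring_rle(mask: int, n: int) -> str:
    """Run-length encode an n-bit clade bitstring (``110000`` -> ``K2L4``)."""
    if n < 1:
        raise ValueError("empty bitstring")
    text = mask_to_text(mask, n)
    out: list[str] = []
    i = 0
    while i < n:
        j = i
        while j < n and text[j] == text[i]:
            j += 1
        out.append(("K" if text[i] == "1" else "L") + str(j - i))
        i = j
    return "".join(out)


def decode_bitstring_rle(text: str, n: int) -> int:
    """Inverse of :func:`encode_bitstring_rle`; run lengths must sum to n."""
    if not re.fullmatch(r"(?:[KL][0-9]+)+", text):
        raise TRZError(f"malformed bitstring run-length text: {text!r}")
    bits: list[str] = []
    prev = ""
    for sym, count in re.findall(r"([KL])([0-9]+)", text):
        if sym == prev:
            raise TRZError(f"non-alternating runs in {text!r}")
        prev = sym
        length = int(count)
        if length == 0:
            raise TRZError(f"zero-length run in {text!r}")
        bits.append(("1" if sym == "K" else "0") * length)
    joined = "".join(bits)
    if len(joined) != n:
        raise TRZError(f"run lengths in {text!r} sum to {len(joined)}, expected {n}")
    return text_to_mask(joined)


# ---------------------------------------------------------------------------
# tree-id list codec


def _rle_deltas(values: Sequence[int]) -> str:
    # first element verbatim, then successive differences; equal
    # consecutive elements of that sequence are run-length compressed
    deltas: list[int] = []
    prev: Optional[int] = None
    for v in values:
        deltas.append(v if prev is None else v - prev)
        prev = v
    out: list[str] = []
    i = 0
    while i < len(deltas):
        j = i
        while j < len(deltas) and deltas[j] == deltas[i]:
            j += 1
        digits = str(deltas[i])
        token = _DIGIT_TO_CHAR[int(digits[0])] + digits[1:]
        if j - i > 1:
            token += "M" + str(j - i)
        out.append(token)
        i = j
    return "".join(out)


def encode_id_list(members: Sequence[int], u: int) -> tuple[str, str]:
    """Encode a strictly increasing id set over universe ``{0..u-1}``.

    The smaller of the set and its complement is listed (ties keep the
    members, sign ``+``); the listed set is delta- then run-length
    encoded with A–J first digits and ``M``-marked run counts.
    """
    members = list(members)
    if any(m < 0 or m >= u for m in members):
        raise ValueError(f"tree id out of range [0, {u})")
    if any(b <= a for a, b in zip(members, members[1:])):
        raise ValueError("member ids must be strictly increasing")
    complement = sorted(set(range(u)) - set(members))
    if len(members) <= len(complement):
        return "+", _rle_deltas(members)
    return "-", _rle_deltas(complement)


def decode_id_list(sign: str, payload: str, u: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_id_list`: the member set, increasing."""
    if sign not in "+-":
        raise TRZError(f"bad id-list sign: {sign!r}")
    if payload and not re.fullmatch(r"(?:[A-J][0-9]*(?:M[0-9]+)?)+", payload):
        raise TRZError(f"malformed id payload: {payload!r}")
    listed: list[int] = []
    for first, rest, count in re.findall(r"([A-J])([0-9]*)(?:M([0-9]+))?", payload):
        value = int(_CHAR_TO_DIGIT[first] + rest)
        repeat = int(count) if count else 1
        if repeat < 1:
            raise TRZError(f"bad run count in payload {payload!r}")
        for _ in range(repeat):
            listed.append(value if not listed else listed[-1] + value)
    if any(b <= a for a, b in zip(listed, listed[1:])):
        raise TRZError(f"payload {payload!r} decodes to a non-increasing id list")
    if listed and listed[-1] >= u:
        raise TRZError(f"decoded id {listed[-1]} outside universe of size {u}")
    if sign == "+":
        return tuple(listed)
    listed_set = set(listed)
    return tuple(i for i in range(u) if i not in listed_set)


# ---------------------------------------------------------------------------
# branch-length codec


def encode_weights(
    lengths: Sequence[Decimal], mantissa_digits: int = 6
) -> tuple[bytes, tuple[tuple[int, int], ...]]:
    """Encode branch lengths at fixed mantissa precision.

    Each length is rounded (half away from zero) to *mantissa_digits*
    fractional digits; the mantissa's two-digit groups, most significant
    first, each become one byte after a +33 offset.  Integral parts are
    almost always zero in this domain, so non-zero ones are returned as
    ``(position, integral)`` exceptions rather than widening every entry.
    """
    if mantissa_digits < 2 or mantissa_digits % 2:
        raise ValueError("mantissa_digits must be even and >= 2")
    payload = bytearray()
    exceptions: list[tuple[int, int]] = []
    for idx, raw in enumerate(lengths):
        if raw < 0:
            raise ValueError(f"negative branch length: {raw}")
        value = quantize_length(Decimal(raw), mantissa_digits)
        integral = int(value)
        if integral >= _MAX_INTEGRAL:
            raise ValueError(f"branch length integral {integral} unsupported")
        mantissa = value - integral  # in [0, 1)
        digits = format(mantissa.scaleb(mantissa_digits), "f")
        digits = digits.rjust(mantissa_digits, "0")
        for k in range(0, mantissa_digits, 2):
            payload.append(int(digits[k : k + 2]) + _WEIGHT_OFFSET)
        if integral > 0:
            exceptions.append((idx, integral))
    return bytes(payload), tuple(exceptions)


def decode_weights(
    payload: bytes,
    exceptions: Sequence[tuple[int, int]],
    count: int,
    mantissa_digits: int = 6,
) -> tuple[Decimal, ...]:
    """Inverse of :func:`encode_weights` at mantissa precision."""
    group_count = mantissa_digits // 2
    if len(payload) != count * group_count:
        raise TRZError(
            f"weight payload holds {len(payload)} bytes, expected {count * group_count}"
        )
    integrals = dict(exceptions)
    if any(i < 0 or i >= count for i in integrals):
        raise TRZError("integral exception index out of range")
    out: list[Decimal] = []
    for idx in range(count):
        digits = []
        for g in range(group_count):
            byte = payload[idx * group_count + g]
            if byte < _WEIGHT_OFFSET or byte > _WEIGHT_OFFSET + 99:
                raise TRZError(f"weight byte {byte} outside the encoded range")
            digits.append(format(byte - _WEIGHT_OFFSET, "02d"))
        mantissa = Decimal("".join(digits)).scaleb(-mantissa_digits)
        out.append(
            quantize_length(mantissa + integrals.get(idx, 0), mantissa_digits)
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# documents


@dataclass(frozen=True)
class TRZHeader:
    taxa: TaxaIndex
    t: int
    u: int
    n_bipartitions: int
    weighted: bool
    mantissa_digits: int = 6

    def __post_init__(self) -> None:
        if self.t < 0 or self.u < 0:
            raise TRZError("negative tree counts")
        if self.t == 0 and self.u != 0:
            raise TRZError("empty collection must have u = 0")
        if self.t > 0 and not (1 <= self.u <= self.t):
            raise TRZError(f"unique count u={self.u} outside [1, t={self.t}]")
        if self.t > 0 and self.n_bipartitions < len(self.taxa):
            raise TRZError("every leaf clade must occur: B >= n when t >= 1")
        if self.mantissa_digits < 2 or self.mantissa_digits % 2:
            raise TRZError("mantissa_digits must be even and >= 2")


@dataclass(frozen=True)
class TRZLine:
    """One unique bipartition: its bitstring, the unique-tree ids that
    contain it, and (weighted documents) their branch lengths in
    increasing id order."""

    mask: int
    members: tuple[int, ...]
    weights: Optional[tuple[Decimal, ...]] = None


@dataclass
class TRZDocument:
    """A parsed TRZ file: header, canonical bipartition lines, and the
    duplicates map (unique id -> all original positions, stored only for
    ids occurring more than once)."""

    header: TRZHeader
    lines: list[TRZLine]
    duplicates: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lines = sorted(self.lines, key=lambda ln: canonical_sort_key(ln.mask))
        self.validate()

    def validate(self) -> None:
        hdr = self.header
        n = len(hdr.taxa)
        if len(self.lines) != hdr.n_bipartitions:
            raise TRZError(
                f"header announces {hdr.n_bipartitions} bipartitions, "
                f"found {len(self.lines)}"
            )
        seen_masks: set[int] = set()
        leaf_masks = {1 << (n - 1 - i) for i in range(n)}
        for line in self.lines:
            if line.mask <= 0 or line.mask >= (1 << n) - 1:
                raise TRZError("bipartition must be a proper non-empty taxon subset")
            if line.mask in seen_masks:
                raise TRZError(f"duplicate bipartition {mask_to_text(line.mask, n)}")
            seen_masks.add(line.mask)
            if not line.members:
                raise TRZError("bipartition with no member trees")
            if any(m < 0 or m >= hdr.u for m in line.members):
                raise TRZError("member id outside [0, u)")
            if any(b <= a for a, b in zip(line.members, line.members[1:])):
                raise TRZError("member ids must be strictly increasing")
            if hdr.weighted:
                if line.weights is None or len(line.weights) != len(line.members):
                    raise TRZError("weighted line must align weights with members")
            elif line.weights is not None:
                raise TRZError("unweighted document carries weights")
            leaf_masks.discard(line.mask)
        if hdr.t > 0 and leaf_masks:
            raise TRZError("missing leaf clade line(s)")
        # duplicates section
        claimed: set[int] = set()
        for uid, positions in self.duplicates.items():
            if uid < 0 or uid >= hdr.u:
                raise TRZError(f"duplicate line for unknown unique id {uid}")
            if len(positions) < 2:
                raise TRZError("duplicate lines must cover at least two positions")
            if any(p < 0 or p >= hdr.t for p in positions):
                raise TRZError("duplicate position outside [0, t)")
            if claimed & set(positions):
                raise TRZError("duplicate lines claim overlapping positions")
            claimed |= set(positions)
        remaining = hdr.t - len(claimed)
        if remaining != hdr.u - len(self.duplicates):
            raise TRZError(
                "duplicate coverage inconsistent: remaining positions do not "
                "match unique ids without duplicate lines"
            )

    def position_map(self) -> list[int]:
        """Unique id of every original position ``0..t-1``.

        Positions claimed by duplicate lines keep their unique id; the
        remaining positions, in increasing order, are assigned to the
        unique ids without duplicate lines in increasing id order (valid
        because unique ids are first-appearance ordered).
        """
        out: dict[int, int] = {}
        for uid, positions in self.duplicates.items():
            for p in positions:
                out[p] = uid
        rest_uids = [uid for uid in range(self.header.u) if uid not in self.duplicates]
        rest_pos = [p for p in range(self.header.t) if p not in out]
        for p, uid in zip(rest_pos, rest_uids):
            out[p] = uid
        return [out[p] for p in range(self.header.t)]


# ---------------------------------------------------------------------------
# serialization


def _render_line(line: TRZLine, n: int, u: int, mantissa_digits: int) -> bytes:
    rle = encode_bitstring_rle(line.mask, n).encode("ascii")
    sign, payload = encode_id_list(line.members, u)
    out = rle + b" " + sign.encode("ascii") + payload.encode("ascii")
    if line.weights is not None:
        wbytes, exceptions = encode_weights(line.weights, mantissa_digits)
        out += b" " + wbytes
        if exceptions:
            out += b" !" + ",".join(f"{i}:{v}" for i, v in exceptions).encode("ascii")
    return out


def write_trz(doc: TRZDocument, stream=None) -> bytes:
    """Serialize a document to TRZ bytes (optionally writing *stream*).

    Output is canonical: any permutation of the in-memory line order
    produces byte-identical files.
    """
    hdr = doc.header
    n = len(hdr.taxa)
    chunks: list[bytes] = [
        " ".join(hdr.taxa.names).encode("ascii"),
        str(hdr.t).encode("ascii"),
        str(hdr.n_bipartitions).encode("ascii"),
        f"U {hdr.u} W {1 if hdr.weighted else 0} K {hdr.mantissa_digits}".encode("ascii"),
    ]
    for line in doc.lines:
        chunks.append(_render_line(line, n, hdr.u, hdr.mantissa_digits))
    for uid in sorted(doc.duplicates):
        sign, payload = encode_id_list(doc.duplicates[uid], hdr.t)
        chunks.append(f"D {uid} {sign}{payload}".encode("ascii"))
    blob = b"\n".join(chunks) + b"\n"
    if stream is not None:
        stream.write(blob)
    return blob


def _parse_bip_line(
    raw: bytes, n: int, u: int, weighted: bool, mantissa_digits: int
) -> TRZLine:
    sp1 = raw.find(b" ")
    if sp1 < 0:
        raise TRZError(f"missing id field: {raw!r}")
    mask = decode_bitstring_rle(raw[:sp1].decode("ascii"), n)
    rest = raw[sp1 + 1 :]
    if not rest:
        raise TRZError(f"missing id field: {raw!r}")
    sign = chr(rest[0])
    sp2 = rest.find(b" ")
    id_field = rest if sp2 < 0 else rest[:sp2]
    tail = b"" if sp2 < 0 else rest[sp2 + 1 :]
    members = decode_id_list(sign, id_field[1:].decode("ascii"), u)
    if not weighted:
        if tail:
            raise TRZError(f"unexpected weight data in unweighted document: {raw!r}")
        return TRZLine(mask=mask, members=members)
    need = len(members) * mantissa_digits // 2
    if len(tail) < need:
        raise TRZError(f"short weight payload on line {raw!r}")
    wbytes, tail = tail[:need], tail[need:]
    exceptions: list[tuple[int, int]] = []
    if tail:
        if not tail.startswith(b" !"):
            raise TRZError(f"unexpected trailing bytes on line {raw!r}")
        for item in tail[2:].decode("ascii").split(","):
            idx_s, _, val_s = item.partition(":")
            try:
                exceptions.append((int(idx_s), int(val_s)))
            except ValueError:
                raise TRZError(f"malformed integral exception {item!r}") from None
    weights = decode_weights(wbytes, exceptions, len(members), mantissa_digits)
    return TRZLine(mask=mask, members=members, weights=weights)


def read_trz(source) -> TRZDocument:
    """Parse TRZ bytes (or a binary stream) into a :class:`TRZDocument`."""
    if isinstance(source, (bytes, bytearray)):
        data = bytes(source)
    else:
        data = source.read()
    raw_lines = data.split(b"\n")
    if raw_lines and raw_lines[-1] == b"":
        raw_lines.pop()
    if len(raw_lines) < 4:
        raise TRZError("truncated TRZ header")
    try:
        taxa = TaxaIndex(tuple(raw_lines[0].decode("ascii").split()))
    except ValueError as exc:
        raise TRZError(f"bad taxa line: {exc}") from None
    try:
        t = int(raw_lines[1])
        n_bip = int(raw_lines[2])
    except ValueError:
        raise TRZError("tree/bipartition counts must be integers") from None
    m = re.fullmatch(rb"U ([0-9]+) W ([01]) K ([0-9]+)", raw_lines[3])
    if not m:
        raise TRZError(f"bad header line 4: {raw_lines[3]!r}")
    u, weighted, mantissa_digits = int(m.group(1)), m.group(2) == b"1", int(m.group(3))
    header = TRZHeader(
        taxa=taxa, t=t, u=u, n_bipartitions=n_bip,
        weighted=weighted, mantissa_digits=mantissa_digits,
    )
    n = len(taxa)
    body = raw_lines[4:]
    if len(body) < n_bip:
        raise TRZError(f"expected {n_bip} bipartition lines, found {len(body)}")
    lines: list[TRZLine] = []
    prev_key = None
    for raw in body[:n_bip]:
        line = _parse_bip_line(raw, n, u, weighted, mantissa_digits)
        key = canonical_sort_key(line.mask)
        if prev_key is not None and key <= prev_key:
            raise TRZError("bipartition lines out of canonical order")
        prev_key = key
        lines.append(line)
    duplicates: dict[int, tuple[int, ...]] = {}
    for raw in body[n_bip:]:
        if not raw.startswith(b"D "):
            raise TRZError(f"unknown section tag on line {raw!r}")
        parts = raw.decode("ascii").split(" ")
        if len(parts) != 3:
            raise TRZError(f"malformed duplicates line {raw!r}")
        uid = int(parts[1])
        if uid in duplicates:
            raise TRZError(f"repeated duplicates line for unique id {uid}")
        positions = decode_id_list(parts[2][0], parts[2][1:], t)
        duplicates[uid] = positions
    return TRZDocument(header=header, lines=lines, duplicates=duplicates)
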