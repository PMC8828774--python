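"""Invertible mapping between commit identifiers and synthesizable DNA barcodes.

A barcode insert carries three fields, reading 5' to 3':

``seed header`` ‖ ``whitened( payload ‖ CRC-16(seed ‖ payload) )``

* The **payload** is the commit identifier (default 40 bits).
* The **checksum** is CRC-16/CCITT-FALSE over ``seed ‖ payload`` (big-endian
  bytes, left-padded to whole bytes), truncated to ``checksum_bits``.
* Payload and checksum bits are XOR-**whitened** with a pad derived from the
  seed by SHA-256 (fixed, documented below) and then written 2 bits/base
  (``00→A 01→C 10→G 11→T``, most-significant bits first).
* The **seed header** (default 8 bits) is written with a homopolymer-free
  base-3 scheme: the first base is ``ACG``[digit], each later base is the
  digit-th of the three bases differing from its predecessor, in alphabetical
  order.  No two adjacent header bases are ever equal.

Encoding tries seeds ``0 .. 2**seed_bits - 1`` in order and keeps the first
whose insert (and full cassette, across the flank junctions) satisfies the
composition constraints: GC fraction bounds, maximal homopolymer run, and a
forbidden-motif screen on both strands.  Because the seed travels inside the
barcode, decoding needs no external registry: parse the header, un-whiten,
check the CRC.  A sequence is accepted as a codeword only if re-encoding the
decoded identifier reproduces it exactly (canonical-codeword rule), which
makes the accepted codeword set exactly the image of ``encode`` and rules out
chance CRC collisions under a corrupted seed header.

Error tolerance: with correction enabled, decode searches the Hamming ball
(substitutions only) of radius ``max_correct`` for a unique codeword; two
codewords at the minimal distance are reported as undecodable, never resolved
silently.  Indels are out of codec scope — reads with indels are handled by
alignment upstream.

Whitening pad: bytes ``SHA-256(b"cellver/whiten/v1" + seed.to_bytes(4,"big")
+ counter.to_bytes(4,"big"))`` for counter 0, 1, ... concatenated as needed;
the pad integer keeps the lowest ``payload_bits + checksum_bits`` bits.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .util import gc_fraction, is_dna, max_homopolymer_run, revcomp

__all__ = [
    "BarcodeSpec",
    "Barcode",
    "Violation",
    "CodecError",
    "EncodingError",
    "DecodeError",
    "UndecodableError",
    "AmbiguousDecodeError",
    "DecodeReport",
    "encode",
    "decode",
    "decode_batch",
    "validate",
    "min_pairwise_distance",
    "crc16_ccitt",
]

# Recognition sites of restriction enzymes in everyday cloning use; screened
# on both strands so that a synthesized cassette stays compatible with
# standard digest-based workflows.
DEFAULT_FORBIDDEN_MOTIFS = frozenset(
    {
        "GAATTC",  # EcoRI
        "GGATCC",  # BamHI
        "AAGCTT",  # HindIII
        "CTGCAG",  # PstI
        "GTCGAC",  # SalI
        "CTCGAG",  # XhoI
        "TCTAGA",  # XbaI
        "ACTAGT",  # SpeI
        "GGTACC",  # KpnI
        "GAGCTC",  # SacI
        "CATATG",  # NdeI
        "CCATGG",  # NcoI
        "GATATC",  # EcoRV
        "GCATGC",  # SphI
        "AGATCT",  # BglII
    }
)

# 20-nt anchor flanks (~50% GC, homopolymer-free beyond runs of 2, motif-free
# on both strands); they double as priming sites for amplicon recovery.
DEFAULT_FLANK_5P = "ATCGCAGTGGTACAGCTTGA"
DEFAULT_FLANK_3P = "TCAAGGTCTGCACTAGCGAT"


class CodecError(ValueError):
    """Base class for codec failures."""


class EncodingError(CodecError):
    """No seed produced a constraint-satisfying insert."""


class DecodeError(CodecError):
    """Base class for decode failures."""


class UndecodableError(DecodeError):
    """No codeword found within the correction radius."""


class AmbiguousDecodeError(UndecodableError):
    """Two or more codewords at the minimal distance — reported, not guessed."""


@dataclass(frozen=True)
class BarcodeSpec:
    """Codec geometry and sequence-composition constraints.

    Defaults give a 34-nt insert (6-nt seed header + 28-nt body) and a 74-nt
    cassette once the two 20-nt flanks are added.
    """

    payload_bits: int = 40
    checksum_bits: int = 16
    seed_bits: int = 8
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_homopolymer: int = 3
    forbidden_motifs: frozenset[str] = DEFAULT_FORBIDDEN_MOTIFS
    flank_5p: str = DEFAULT_FLANK_5P
    flank_3p: str = DEFAULT_FLANK_3P
    max_correct: int = 2

    def __post_init__(self) -> None:
        if self.payload_bits < 1:
            raise ValueError("payload_bits must be >= 1")
        if not 1 <= self.checksum_bits <= 16:
            raise ValueError("checksum_bits must be in 1..16 (CRC-16 based)")
        if not 1 <= self.seed_bits <= 16:
            raise ValueError("seed_bits must be in 1..16")
        if (self.payload_bits + self.checksum_bits) % 2:
            raise ValueError("payload_bits + checksum_bits must be even (2 bits/base)")
        if self.payload_bits + self.checksum_bits > 64:
            raise ValueError("payload_bits + checksum_bits must be <= 64")
        if not 0.0 <= self.gc_min < self.gc_max <= 1.0:
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")
        if self.max_correct < 0:
            raise ValueError("max_correct must be >= 0")
        object.__setattr__(
            self, "forbidden_motifs", frozenset(m.upper() for m in self.forbidden_motifs)
        )
        for name in ("flank_5p", "flank_3p"):
            seq = getattr(self, name).upper()
            if seq and not is_dna(seq):
                raise ValueError(f"{name} is not a DNA string")
            object.__setattr__(self, name, seq)
        for name in ("flank_5p", "flank_3p"):
            seq = getattr(self, name)
            if seq and _flank_violations(seq, self):
                raise ValueError(f"{name} violates the spec's own composition constraints")

    @property
    def header_len(self) -> int:
        n = 1
        while 3**n < (1 << self.seed_bits):
            n += 1
        return n

    @property
    def body_len(self) -> int:
        return (self.payload_bits + self.checksum_bits) // 2

    @property
    def insert_len(self) -> int:
        return self.header_len + self.body_len

    @property
    def cassette_len(self) -> int:
        return len(self.flank_5p) + self.insert_len + len(self.flank_3p)

    @property
    def digest(self) -> str:
        key = (
            f"{self.payload_bits},{self.checksum_bits},{self.seed_bits},"
            f"{self.gc_min},{self.gc_max},{self.max_homopolymer},"
            f"{','.join(sorted(self.forbidden_motifs))},"
            f"{self.flank_5p},{self.flank_3p},{self.max_correct}"
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Barcode:
    commit_uid: int
    insert: str
    cassette: str
    spec_digest: str
    seed_used: int


@dataclass(frozen=True)
class Violation:
    kind: str  # "gc" | "homopolymer" | "motif" | "alphabet"
    position: int | None
    detail: str


@dataclass(frozen=True)
class DecodeReport:
    distance: int
    corrected_positions: tuple[int, ...]
    checksum_ok: bool


# ---------------------------------------------------------------------------
# CRC-16/CCITT-FALSE (poly 0x1021, init 0xFFFF, no reflection, no xor-out)

def _make_crc_table() -> np.ndarray:
    table = np.zeros(256, dtype=np.uint32)
    for i in range(256):
        crc = i << 8
        for _ in range(8):
            crc = ((crc << 1) ^ 0x1021) if crc & 0x8000 else (crc << 1)
            crc &= 0xFFFF
        table[i] = crc
    return table


_CRC_TABLE = _make_crc_table()


def crc16_ccitt(data: bytes) -> int:
    crc = 0xFFFF
    for byte in data:
        crc = ((crc << 8) & 0xFFFF) ^ int(_CRC_TABLE[((crc >> 8) ^ byte) & 0xFF])
    return crc


# ---------------------------------------------------------------------------
# bit/base plumbing

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _checksum(uid: int, seed: int, spec: BarcodeSpec) -> int:
    msg = (seed << spec.payload_bits) | uid
    nbytes = (spec.seed_bits + spec.payload_bits + 7) // 8
    return crc16_ccitt(msg.to_bytes(nbytes, "big")) & ((1 << spec.checksum_bits) - 1)


def _pad_int(seed: int, bits: int) -> int:
    nbytes = (bits + 7) // 8
    out = b""
    counter = 0
    while len(out) < nbytes:
        out += hashlib.sha256(
            b"cellver/whiten/v1" + seed.to_bytes(4, "big") + counter.to_bytes(4, "big")
        ).digest()
        counter += 1
    return int.from_bytes(out[:nbytes], "big") & ((1 << bits) - 1)


def _encode_header(seed: int, spec: BarcodeSpec) -> str:
    digits = []
    v = seed
    for _ in range(spec.header_len):
        digits.append(v % 3)
        v //= 3
    digits.reverse()
    bases = [digits[0]]  # first digit indexes A/C/G
    for d in digits[1:]:
        prev = bases[-1]
        bases.append(d + 1 if d >= prev else d)
    return "".join(_BASES[b] for b in bases)


def _decode_header(seq: str, spec: BarcodeSpec) -> int | None:
    b0 = _BASE_INDEX[seq[0]]
    if b0 == 3:
        return None
    value = b0
    prev = b0
    for ch in seq[1:]:
        cur = _BASE_INDEX[ch]
        if cur == prev:
            return None
        value = value * 3 + (cur - 1 if cur > prev else cur)
        prev = cur
    return value if value < (1 << spec.seed_bits) else None


def _bits_to_dna(value: int, nbases: int) -> str:
    return "".join(_BASES[(value >> (2 * (nbases - 1 - i))) & 3] for i in range(nbases))


def _dna_to_bits(seq: str) -> int:
    value = 0
    for ch in seq:
        value = (value << 2) | _BASE_INDEX[ch]
    return value


def _assemble_insert(uid: int, seed: int, spec: BarcodeSpec) -> str:
    body = (uid << spec.checksum_bits) | _checksum(uid, seed, spec)
    body ^= _pad_int(seed, spec.payload_bits + spec.checksum_bits)
    return _encode_header(seed, spec) + _bits_to_dna(body, spec.body_len)


# ---------------------------------------------------------------------------
# validation

def validate(seq: str, spec: BarcodeSpec) -> list[Violation]:
    """Report every composition-constraint violation in ``seq``.

    Checks GC bounds, homopolymer runs longer than ``max_homopolymer``, and
    forbidden motifs on both strands (positions are forward-strand 0-based).
    """
    violations: list[Violation] = []
    s = seq.upper()
    for pos, ch in enumerate(s):
        if ch not in _BASE_INDEX:
            violations.append(Violation("alphabet", pos, f"non-DNA character {ch!r}"))
    if violations:
        return violations
    gc = gc_fraction(s)
    if not spec.gc_min <= gc <= spec.gc_max:
        violations.append(
            Violation("gc", None, f"GC fraction {gc:.3f} outside [{spec.gc_min}, {spec.gc_max}]")
        )
    violations.extend(_homopolymer_violations(s, spec.max_homopolymer))
    violations.extend(_motif_violations(s, spec.forbidden_motifs))
    return violations


def _homopolymer_violations(s: str, max_run: int) -> list[Violation]:
    out = []
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        if j - i > max_run:
            out.append(Violation("homopolymer", i, f"run of {j - i} x {s[i]} (max {max_run})"))
        i = j
    return out


def _motif_violations(s: str, motifs: Iterable[str]) -> list[Violation]:
    hits: set[tuple[int, str, str]] = set()
    for motif in motifs:
        for query, strand in ((motif, "+"), (revcomp(motif), "-")):
            start = s.find(query)
            while start != -1:
                hits.add((start, motif, strand))
                start = s.find(query, start + 1)
    return [
        Violation("motif", pos, f"forbidden motif {motif} ({strand} strand)")
        for pos, motif, strand in sorted(hits)
    ]


def _flank_violations(flank: str, spec: BarcodeSpec) -> list[Violation]:
    # Flanks are fixed anchors: homopolymer and motif rules apply verbatim;
    # GC is checked on the flank itself (it must not drag the cassette out).
    out = _homopolymer_violations(flank, spec.max_homopolymer)
    out += _motif_violations(flank, spec.forbidden_motifs)
    gc = gc_fraction(flank)
    if not spec.gc_min <= gc <= spec.gc_max:
        out.append(Violation("gc", None, f"flank GC {gc:.3f}"))
    return out


def _cassette_junction_violations(barcoded: str, spec: BarcodeSpec) -> list[Violation]:
    # GC is a global composition property of the insert; across the junctions
    # only run-length and motif constraints are meaningful.
    out = _homopolymer_violations(barcoded, spec.max_homopolymer)
    out += _motif_violations(barcoded, spec.forbidden_motifs)
    return out


# ---------------------------------------------------------------------------
# encode / decode

@lru_cache(maxsize=65536)
def _encode_insert(uid: int, spec: BarcodeSpec) -> tuple[str, int]:
    """(insert, seed) for the first constraint-satisfying seed; raises EncodingError."""
    seen_kinds: set[str] = set()
    for seed in range(1 << spec.seed_bits):
        insert = _assemble_insert(uid, seed, spec)
        bad = validate(insert, spec)
        if not bad:
            bad = _cassette_junction_violations(
                spec.flank_5p + insert + spec.flank_3p, spec
            )
        if not bad:
            return insert, seed
        seen_kinds.update(v.kind for v in bad)
    raise EncodingError(
        f"no seed in 0..{(1 << spec.seed_bits) - 1} satisfies the constraints for uid "
        f"{uid}; violated: {', '.join(sorted(seen_kinds))}"
    )


def encode(commit_uid: int, spec: BarcodeSpec | None = None) -> Barcode:
    """Encode a commit identifier into a DNA barcode.

    Deterministic: the same ``(commit_uid, spec)`` always yields the same
    insert.  Raises :class:`EncodingError` when no whitening seed yields a
    constraint-satisfying sequence.
    """
    spec = spec or BarcodeSpec()
    if not 0 <= commit_uid < (1 << spec.payload_bits):
        raise ValueError(f"uid {commit_uid} does not fit in {spec.payload_bits} bits")
    insert, seed = _encode_insert(commit_uid, spec)
    return Barcode(
        commit_uid=commit_uid,
        insert=insert,
        cassette=spec.flank_5p + insert + spec.flank_3p,
        spec_digest=spec.digest,
        seed_used=seed,
    )


def _attempt(seq: str, spec: BarcodeSpec) -> int | None:
    """Parse ``seq`` as a codeword; return the uid or None.

    Accepts only *canonical* codewords: the CRC must verify and re-encoding
    the decoded uid must reproduce ``seq`` exactly.
    """
    seed = _decode_header(seq[: spec.header_len], spec)
    if seed is None:
        return None
    body = _dna_to_bits(seq[spec.header_len :])
    body ^= _pad_int(seed, spec.payload_bits + spec.checksum_bits)
    checksum = body & ((1 << spec.checksum_bits) - 1)
    uid = body >> spec.checksum_bits
    if _checksum(uid, seed, spec) != checksum:
        return None
    try:
        insert, _ = _encode_insert(uid, spec)
    except EncodingError:
        return None
    return uid if insert == seq else None


def decode(
    seq: str, spec: BarcodeSpec | None = None, allow_correction: bool = False
) -> tuple[int, DecodeReport]:
    """Decode a barcode insert back to its commit identifier.

    Exact inverse of :func:`encode` on unmutated input.  With
    ``allow_correction`` the Hamming ball of radius ``spec.max_correct`` is
    searched for a unique codeword; ties at the minimal distance raise
    :class:`AmbiguousDecodeError` (a subclass of :class:`UndecodableError`).
    """
    spec = spec or BarcodeSpec()
    s = seq.upper()
    if len(s) != spec.insert_len:
        raise DecodeError(f"expected insert of length {spec.insert_len}, got {len(s)}")
    if any(ch not in _BASE_INDEX for ch in s):
        raise DecodeError("sequence contains non-ACGT characters")
    uid = _attempt(s, spec)
    if uid is not None:
        return uid, DecodeReport(distance=0, corrected_positions=(), checksum_ok=True)
    if not allow_correction:
        raise UndecodableError("checksum failed and correction disabled")
    for dist in range(1, spec.max_correct + 1):
        hits: list[tuple[str, tuple[int, ...], int]] = []
        for positions in itertools.combinations(range(spec.insert_len), dist):
            originals = [s[p] for p in positions]
            for repl in itertools.product(*(
                [b for b in _BASES if b != orig] for orig in originals
            )):
                cand = list(s)
                for p, b in zip(positions, repl):
                    cand[p] = b
                cand_s = "".join(cand)
                cand_uid = _attempt(cand_s, spec)
                if cand_uid is not None:
                    hits.append((cand_s, positions, cand_uid))
        if len(hits) == 1:
            cand_s, positions, cand_uid = hits[0]
            return cand_uid, DecodeReport(
                distance=dist, corrected_positions=positions, checksum_ok=True
            )
        if len(hits) > 1:
            raise AmbiguousDecodeError(
                f"{len(hits)} codewords at Hamming distance {dist}; refusing to guess"
            )
    raise UndecodableError(
        f"no codeword within Hamming distance {spec.max_correct}"
    )


# ---------------------------------------------------------------------------
# vectorized batch decoding (used for read sets and exhaustive audits)

_SEQ_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _SEQ_LUT[ord(_b)] = _i
    _SEQ_LUT[ord(_b.lower())] = _i


def _seqs_to_array(seqs: Sequence[str], length: int) -> np.ndarray:
    raw = "".join(seqs).encode("ascii")
    arr = _SEQ_LUT[np.frombuffer(raw, dtype=np.uint8)]
    return arr.reshape(len(seqs), length)


@lru_cache(maxsize=8)
def _batch_tables(spec: BarcodeSpec) -> np.ndarray:
    bits = spec.payload_bits + spec.checksum_bits
    return np.array(
        [_pad_int(seed, bits) for seed in range(1 << spec.seed_bits)], dtype=np.uint64
    )


def _batch_attempt(arr: np.ndarray, spec: BarcodeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized codeword parse (CRC check only; canonical check is separate)."""
    n = arr.shape[0]
    hl = spec.header_len
    ok = np.all(arr < 4, axis=1)
    h = arr[:, :hl].astype(np.int64)
    ok &= h[:, 0] < 3
    seed = h[:, 0].copy()
    for i in range(1, hl):
        cur, prev = h[:, i], h[:, i - 1]
        ok &= cur != prev
        seed = seed * 3 + np.where(cur > prev, cur - 1, cur)
    ok &= seed < (1 << spec.seed_bits)
    seed_safe = np.where(ok, seed, 0)

    body = np.zeros(n, dtype=np.uint64)
    b = arr[:, hl:].astype(np.uint64)
    for i in range(spec.body_len):
        body |= b[:, i] << np.uint64(2 * (spec.body_len - 1 - i))
    body ^= _batch_tables(spec)[seed_safe]
    ck_mask = np.uint64((1 << spec.checksum_bits) - 1)
    checksum = body & ck_mask
    payload = body >> np.uint64(spec.checksum_bits)

    msg = (seed_safe.astype(np.uint64) << np.uint64(spec.payload_bits)) | payload
    nbytes = (spec.seed_bits + spec.payload_bits + 7) // 8
    crc = np.full(n, 0xFFFF, dtype=np.uint32)
    for k in range(nbytes - 1, -1, -1):
        byte = ((msg >> np.uint64(8 * k)) & np.uint64(0xFF)).astype(np.uint32)
        idx = ((crc >> 8) ^ byte) & 0xFF
        crc = ((crc << 8) & 0xFFFF) ^ _CRC_TABLE[idx]
    ok &= (crc & np.uint32((1 << spec.checksum_bits) - 1)) == checksum.astype(np.uint32)
    return payload.astype(np.int64), ok


def _canonical_mask(
    arr: np.ndarray, uids: np.ndarray, ok: np.ndarray, spec: BarcodeSpec,
    cache: dict[int, np.ndarray | None],
) -> np.ndarray:
    """Restrict CRC-valid rows to canonical codewords (re-encode comparison)."""
    out = ok.copy()
    rows = np.nonzero(ok)[0]
    if rows.size == 0:
        return out
    uniq, inverse = np.unique(uids[rows], return_inverse=True)
    enc_matrix = np.full((len(uniq), spec.insert_len), 255, dtype=np.uint8)
    for j, uid in enumerate(uniq):
        uid = int(uid)
        enc = cache.get(uid, False)
        if enc is False:
            try:
                insert, _ = _encode_insert(uid, spec)
                enc = _seqs_to_array([insert], spec.insert_len)[0]
            except EncodingError:
                enc = None
            cache[uid] = enc
        if enc is not None:
            enc_matrix[j] = enc
    valid = np.all(arr[rows] == enc_matrix[inverse], axis=1)
    out[rows[~valid]] = False
    return out


def decode_batch(
    seqs: Sequence[str],
    spec: BarcodeSpec | None = None,
    max_correct: int = 1,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Decode many equal-length inserts at once.

    Returns ``(uids, distances)`` aligned with ``seqs``; undecodable or
    ambiguous entries carry uid ``-1`` and distance ``-1``.  Distances 0 and 1
    are resolved vectorized; larger radii fall back to the scalar decoder.
    """
    spec = spec or BarcodeSpec()
    n = len(seqs)
    uids = np.full(n, -1, dtype=np.int64)
    dists = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return uids, dists
    if any(len(s) != spec.insert_len for s in seqs):
        raise DecodeError(f"all sequences must have length {spec.insert_len}")
    arr = _seqs_to_array(seqs, spec.insert_len)
    cache: dict[int, np.ndarray | None] = {}

    u0, ok0 = _batch_attempt(arr, spec)
    ok0 = _canonical_mask(arr, u0, ok0, spec, cache)
    uids[ok0] = u0[ok0]
    dists[ok0] = 0

    if max_correct >= 1:
        pending = np.nonzero(~ok0)[0]
        L = spec.insert_len
        for lo in range(0, len(pending), chunk):
            idx = pending[lo : lo + chunk]
            sub = arr[idx]  # (m, L)
            m = len(idx)
            mut = np.repeat(sub[:, None, :], 3 * L, axis=1)  # (m, 3L, L)
            for p in range(L):
                for a in range(3):
                    mut[:, 3 * p + a, p] = (sub[:, p] + a + 1) % 4
            flat = mut.reshape(m * 3 * L, L)
            u1, ok1 = _batch_attempt(flat, spec)
            ok1 = _canonical_mask(flat, u1, ok1, spec, cache)
            ok1 = ok1.reshape(m, 3 * L)
            u1 = u1.reshape(m, 3 * L)
            nvalid = ok1.sum(axis=1)
            # exactly one codeword at distance 1: unambiguous recovery; two
            # distinct mutants are distinct sequences, hence distinct
            # canonical codewords -> ambiguous, left undecoded.
            unique = np.nonzero(nvalid == 1)[0]
            for r in unique:
                c = int(np.nonzero(ok1[r])[0][0])
                uids[idx[r]] = u1[r, c]
                dists[idx[r]] = 1

    if max_correct >= 2:
        for i in np.nonzero(uids < 0)[0]:
            try:
                uid, report = decode(
                    seqs[i], replace(spec, max_correct=max_correct), allow_correction=True
                )
            except DecodeError:
                continue
            uids[i] = uid
            dists[i] = report.distance
    return uids, dists


# ---------------------------------------------------------------------------

def min_pairwise_distance(barcodes: Sequence[Barcode | str]) -> int:
    """Minimum Hamming distance over all pairs of barcode inserts."""
    seqs = [b.insert if isinstance(b, Barcode) else str(b) for b in barcodes]
    if len(seqs) < 2:
        raise ValueError("need at least two barcodes")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("barcode inserts differ in length")
    arr = _seqs_to_array([s.upper() for s in seqs], length)
    best = length
    for i in range(len(seqs) - 1):
        best = min(best, int((arr[i + 1 :] != arr[i]).sum(axis=1).min()))
        if best == 0:
            return 0
    return best


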