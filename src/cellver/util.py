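"""Small shared helpers: DNA strings, Crockford base-32 identifiers, canonical JSON."""

from __future__ import annotations

import json
import re
from typing import Any

DNA_ALPHABET = "ACGT"
_DNA_RE = re.compile(r"^[ACGTacgt]+$")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Crockford base-32: no I, L, O, U — unambiguous when read off a tube label.
CROCKFORD = "0123456789ABCDEFGHJKMNPQRSTVWXYZ"
_CROCKFORD_INV = {c: i for i, c in enumerate(CROCKFORD)}


def is_dna(seq: str) -> bool:
    return bool(seq) and _DNA_RE.match(seq) is not None


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = None
    for base in seq.upper():
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


def uid_to_str(uid: int, bits: int = 40) -> str:
    """Render an identifier as fixed-width Crockford base-32 (5 bits/char)."""
    if uid < 0 or uid >= 1 << bits:
        raise ValueError(f"uid {uid} does not fit in {bits} bits")
    width = (bits + 4) // 5
    chars = []
    for _ in range(width):
        chars.append(CROCKFORD[uid & 0x1F])
        uid >>= 5
    return "".join(reversed(chars))


def str_to_uid(text: str) -> int:
    value = 0
    for c in text.upper():
        try:
            value = (value << 5) | _CROCKFORD_INV[c]
        except KeyError:
            raise ValueError(f"invalid Crockford base-32 character {c!r}") from None
    return value


def canonical_json(obj: Any) -> str:
    """Stable serialization: sorted keys, 2-space indent, LF, trailing newline."""
    return json.dumps(obj, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def dump_canonical_json(obj: Any, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(canonical_json(obj))
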