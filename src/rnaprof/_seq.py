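"""Sequence normalization and integer encoding shared across modules."""

from __future__ import annotations

import numpy as np

#: Canonical residue alphabet; index in this string is the internal code.
ALPHABET = "ACGUN"

A, C, G, U, N = range(5)

_NORMALIZE = {c: c for c in "ACGUN"}
_NORMALIZE["T"] = "U"

#: Base-pair types in the conventional parameter-table order.
PAIR_NAMES = ("CG", "GC", "GU", "UG", "AU", "UA")

# pair_type[a, b] -> 0..5 for canonical pairs, -1 otherwise (incl. any N)
PAIR_TYPE = -np.ones((5, 5), dtype=np.int8)
for _t, (_x, _y) in enumerate(PAIR_NAMES):
    PAIR_TYPE["ACGUN".index(_x), "ACGUN".index(_y)] = _t


def normalize(seq: str) -> str:
    """Uppercase, DNA thymine to uracil, anything unrecognized to N.

    Returns the normalized sequence string over {A, C, G, U, N}.
    """
    return "".join(_NORMALIZE.get(ch, "N") for ch in seq.upper())


def count_unknown(seq: str) -> int:
    """Number of characters that `normalize` maps to N (excluding real Ns)."""
    up = seq.upper()
    return sum(1 for ch in up if ch not in _NORMALIZE and ch != "N")


def encode(seq: str) -> np.ndarray:
    """Encode a normalized sequence into int8 codes (A=0, C=1, G=2, U=3, N=4)."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        out[i] = ALPHABET.index(ch)
    return out


def pair_type(a: int, b: int) -> int:
    """Pair type of bases with codes ``a`` (5') and ``b`` (3'); -1 if not canonical."""
    return int(PAIR_TYPE[a, b])
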