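"""Desk-scale ground truth by exhaustive structure enumeration.

Enumerates every pseudoknot-free secondary structure of a short sequence,
classifies each base's context from the loop-polygon definitions, scores
structures with the same per-loop free energies as the dynamic program
(shared through :mod:`rnaprof.energy`, but with an independent
loop-decomposition), and forms the exact Boltzmann profile.  Exponential in
the length; guarded to short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._seq import PAIR_TYPE, encode, normalize
from . import energy as en
from .energy import DEFAULT_LOOP_CAP, EnergyParameters
from .profile import CONTEXTS, StructuralProfile

__all__ = ["SecondaryStructure", "enumerate_structures", "classify_contexts",
           "structure_energy", "exact_profile", "MAX_ENUMERATION_LENGTH"]

MAX_ENUMERATION_LENGTH = 16


@dataclass(frozen=True)
class SecondaryStructure:
    """One secondary structure as a dot-bracket string."""

    dotbracket: str

    @property
    def pairs(self) -> tuple:
        """Sorted tuple of 0-based (i, j) pairs."""
        stack = []
        out = []
        for k, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(k)
            elif ch == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket")
                out.append((stack.pop(), k))
            elif ch != ".":
                raise ValueError(f"bad dot-bracket character {ch!r}")
        if stack:
            raise ValueError("unbalanced dot-bracket")
        return tuple(sorted(out))

    def __len__(self) -> int:
        return len(self.dotbracket)


def _pairs_to_dotbracket(pairs, n: int) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i] = "("
        s[j] = ")"
    return "".join(s)


def enumerate_structures(seq, W: int | None = None,
                         max_len: int = MAX_ENUMERATION_LENGTH) -> list:
    """All structures with canonical pairs, hairpins >= 3, span <= W.

    The span constraint matches the dynamic program: a pair (i, j) is
    admissible when its paired region covers at most W bases
    (``j - i + 1 <= W`` in 0-based positions).  Includes the open chain.
    """
    s = normalize(seq) if isinstance(seq, str) else \
        "".join("ACGUN"[c] for c in seq)
    n = len(s)
    if n > max_len:
        raise ValueError(
            f"sequence of length {n} exceeds the enumeration guard "
            f"({max_len})")
    codes = encode(s)
    Wv = n if W is None else max(1, min(int(W), n))

    @lru_cache(maxsize=None)
    def enum(lo: int, hi: int) -> tuple:
        # structures (as pair tuples) of the half-open interval [lo, hi)
        if hi - lo <= 4:
            return ((),)
        out = list(enum(lo + 1, hi))  # lo unpaired
        for k in range(lo + 4, hi):
            if k - lo + 1 > Wv:
                break
            if PAIR_TYPE[codes[lo], codes[k]] < 0:
                continue
            for a in enum(lo + 1, k):
                for b in enum(k + 1, hi):
                    out.append(((lo, k),) + a + b)
        return tuple(out)

    res = [SecondaryStructure(_pairs_to_dotbracket(p, n))
           for p in enum(0, n)]
    enum.cache_clear()
    return res


def classify_contexts(structure: SecondaryStructure) -> str:
    """Context label (one of B, E, H, I, M, S) per base.

    Paired bases are stems.  An unpaired base not enclosed by any pair is
    exterior.  Otherwise the loop polygon closed by the innermost enclosing
    pair decides: one closing bond only -> hairpin; two bonds -> bulge when
    they are joined by a single backbone edge on one side (an empty side),
    internal otherwise; more than two bonds -> multibranch.
    """
    n = len(structure)
    pairs = structure.pairs
    labels = ["E"] * n
    children: dict = {None: []}
    stack: list = [None]
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    opens = {i for i, _ in pairs}
    closes = {j for _, j in pairs}
    enclosing = [None] * n
    for k in range(n):
        if k in opens:
            children.setdefault((k, partner[k]), [])
            children[stack[-1]].append((k, partner[k]))
            stack.append((k, partner[k]))
        elif k in closes:
            stack.pop()
        else:
            enclosing[k] = stack[-1]
    for k in range(n):
        if k in partner:
            labels[k] = "S"
        elif enclosing[k] is not None:
            a, b = enclosing[k]
            kids = children[(a, b)]
            if not kids:
                labels[k] = "H"
            elif len(kids) == 1:
                (c, d), = kids
                labels[k] = "B" if (c - a - 1 == 0 or b - d - 1 == 0) else "I"
            else:
                labels[k] = "M"
    return "".join(labels)


def structure_energy(seq, structure: SecondaryStructure,
                     params: EnergyParameters,
                     loop_cap: int = DEFAULT_LOOP_CAP) -> float:
    """Free energy (kcal/mol) relative to the open chain.

    Decomposes the structure into loops and sums the same per-loop
    energies used by the dynamic program: hairpin, stack, bulge/internal
    (capped at ``loop_cap`` total unpaired bases), affine multibranch
    terms, and the terminal-AU penalty at exterior/multibranch helix ends.
    Returns ``inf`` for structures outside the model (e.g. over-long
    internal loops).
    """
    s = normalize(seq) if isinstance(seq, str) else \
        "".join("ACGUN"[c] for c in seq)
    pairs = structure.pairs
    if not pairs:
        return 0.0
    children: dict = {None: []}
    stack: list = [None]
    opens = {i: j for i, j in pairs}
    closes = {j for _, j in pairs}
    unpaired_within: dict = {p: 0 for p in pairs}
    unpaired_within[None] = 0
    for k in range(len(s)):
        if k in opens:
            node = (k, opens[k])
            children.setdefault(node, [])
            children[stack[-1]].append(node)
            stack.append(node)
        elif k in closes:
            stack.pop()
        else:
            unpaired_within[stack[-1]] += 1
    e = 0.0
    for i, j in pairs:
        kids = children[(i, j)]
        if not kids:
            e += en.hairpin_energy(s, i, j, params)
        elif len(kids) == 1:
            (p, q), = kids
            if p == i + 1 and q == j - 1:
                e += en.stack_energy(s, i, j, params)
            else:
                e += en.interior_energy(s, i, j, p, q, params, loop_cap)
        else:
            e += en.multiloop_close_energy(s, i, j, params)
            for p, q in kids:
                e += en.multiloop_branch_energy(s, p, q, params)
            e += unpaired_within[(i, j)] * en.multiloop_unpaired_energy(
                params)
    for p, q in children[None]:
        e += en.external_branch_energy(s, p, q, params)
    return e


def exact_profile(seq, params: EnergyParameters | None = None,
                  W: int | None = None, loop_cap: int = DEFAULT_LOOP_CAP,
                  name: str = "seq") -> StructuralProfile:
    """Exact Boltzmann structural profile by full enumeration."""
    if params is None:
        params = en.load_parameters("default")
    s = normalize(seq) if isinstance(seq, str) else \
        "".join("ACGUN"[c] for c in seq)
    n = len(s)
    structures = enumerate_structures(s, W)
    acc = np.zeros((n, 6))
    z = 0.0
    col = {c: k for k, c in enumerate(CONTEXTS)}
    for st in structures:
        w = en.boltzmann_weight(structure_energy(s, st, params, loop_cap),
                                params)
        if w == 0.0:
            continue
        z += w
        for r, lab in enumerate(classify_contexts(st)):
            acc[r, col[lab]] += w
    Wv = n if W is None else min(int(W), n)
    return StructuralProfile(name, s, acc / z, Wv)
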