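"""Nearest-neighbor thermodynamic model for RNA secondary structure.

This module houses the Turner free-energy tables and converts loop and stack
free energies into Boltzmann weights for the folding grammar transitions.
Energies are stored in kcal/mol at 0.01 kcal resolution; weights are
``exp(-dG / RT)`` with a forbidden configuration mapping to weight 0
(energy ``+inf``).

The bundled default parameter set is the published Turner 2004 free energies
in the de-facto standard Vienna text dialect (``## RNAfold parameter file
v2.0``).  Only 37 degC free energies are used; enthalpies are ignored, so a
temperature override rescales RT but not the energies themselves.

Conventions (applied identically by the dynamic program and by the
enumeration oracle, which share this module):

* minimum hairpin loop: 3 unpaired bases;
* hairpin loops: length term (log-extrapolated beyond 30) plus terminal
  mismatch for loops > 3; loops of exactly 3 get the terminal-AU penalty
  instead; tabulated special tri-/tetra-/hexaloops replace the whole term;
* bulge loops: length term; a bulge of 1 additionally stacks its two
  closing pairs, longer bulges pay the terminal-AU penalty at both ends;
* internal loops: tabulated 1x1, 1x2, 2x2 values where available, otherwise
  length term + Ninio asymmetry (capped) + one terminal mismatch per side
  (the dedicated 1xn/2x3 mismatch variants are folded into the generic
  internal mismatch table);
* multibranch loops: affine model ``a`` (closing) + ``b`` per branch
  (closing pair included) + ``c`` per unpaired base, with the terminal-AU
  penalty per non-GC helix end in the loop;
* exterior loops: unpaired bases are free; each helix meeting the exterior
  loop pays only the terminal-AU penalty;
* no dangling-end or coaxial-stacking contributions: the grammar emits no
  dangle states, and keeping the energies strictly loop-local keeps the
  dynamic program exact with respect to the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from ._seq import PAIR_TYPE, encode, normalize

#: kcal / (mol K)
GAS_CONSTANT = 1.98717e-3
#: 37 degC, the temperature at which the bundled free energies are defined.
DEFAULT_TEMPERATURE = 310.15
#: Maximal total unpaired length of internal/bulge loops (folding default).
DEFAULT_LOOP_CAP = 30
#: Coefficient of the logarithmic loop-length extrapolation (kcal/mol).
DEFAULT_LXC = 1.07856

_INF = np.inf


class ParameterError(ValueError):
    """Raised for unreadable or malformed parameter files."""


@dataclass
class EnergyParameters:
    """Thermodynamic parameter set (all energies in kcal/mol).

    Tables follow the conventional layout: pair types are indexed
    0..5 = CG, GC, GU, UG, AU, UA (index 6 holds the unspecified-pair row
    where the source dialect provides one), and single bases are indexed
    1..4 = A, C, G, U with 0 reserved for N / "no mismatch".
    """

    stack: np.ndarray                 # (7, 7)
    hairpin_by_length: np.ndarray     # (31,), lengths 0..30, <3 forbidden
    hairpin_mismatch: np.ndarray      # (7, 5, 5)
    bulge_by_length: np.ndarray       # (31,)
    internal_by_length: np.ndarray    # (31,)
    internal_mismatch: np.ndarray     # (7, 5, 5)
    internal_asymmetry: float         # Ninio penalty per unpaired-length diff
    internal_asymmetry_max: float     # cap on the asymmetry penalty
    int11: np.ndarray                 # (7, 7, 5, 5)
    int21: np.ndarray                 # (7, 7, 5, 5, 5)
    int22: np.ndarray                 # (6, 6, 4, 4, 4, 4)
    multiloop_close: float            # a: closing a multibranch loop
    multiloop_branch: float           # b: per branch (closing pair included)
    multiloop_unpaired: float         # c: per unpaired loop base
    terminal_au: float                # per non-GC helix end
    lxc: float = DEFAULT_LXC
    special_hairpins: dict = field(default_factory=dict)
    temperature_K: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature_K

    def __eq__(self, other) -> bool:
        if not isinstance(other, EnergyParameters):
            return NotImplemented
        for name in ("stack", "hairpin_by_length", "hairpin_mismatch",
                     "bulge_by_length", "internal_by_length",
                     "internal_mismatch", "int11", "int21", "int22"):
            if not np.array_equal(getattr(self, name), getattr(other, name)):
                return False
        scalars = ("internal_asymmetry", "internal_asymmetry_max",
                   "multiloop_close", "multiloop_branch", "multiloop_unpaired",
                   "terminal_au", "lxc", "temperature_K", "gas_constant")
        return (all(getattr(self, n) == getattr(other, n) for n in scalars)
                and self.special_hairpins == other.special_hairpins)


# ---------------------------------------------------------------------------
# Parameter file I/O (Vienna-style text dialect)
# ---------------------------------------------------------------------------

_MATRIX_BLOCKS = {
    "stack": (7, 7),
    "mismatch_hairpin": (7, 5, 5),
    "mismatch_internal": (7, 5, 5),
    "int11": (7, 7, 5, 5),
    "int21": (7, 7, 5, 5, 5),
    "int22": (6, 6, 4, 4, 4, 4),
    "hairpin": (31,),
    "bulge": (31,),
    "internal": (31,),
}
_SPECIAL_BLOCKS = ("Triloops", "Tetraloops", "Hexaloops")


def _tokenize(text: str) -> dict:
    """Split a parameter file into blocks of raw lines keyed by block name."""
    import re

    text = re.sub(r"/\*.*?\*/", " ", text, flags=re.S)
    blocks: dict[str, list[str]] = {}
    name = None
    for line in text.splitlines():
        if line.startswith("# "):
            name = line[2:].strip()
            blocks.setdefault(name, [])
        elif name is not None and line.strip() and not line.startswith("#"):
            blocks[name].append(line)
    return blocks


def _parse_numbers(name: str, lines: list[str]) -> np.ndarray:
    vals = []
    for line in lines:
        for tok in line.split():
            if tok == "#END":
                continue
            if tok.upper() in ("INF", "NST", "DEF"):
                vals.append(_INF)
            else:
                try:
                    vals.append(float(tok) / 100.0)
                except ValueError as exc:
                    raise ParameterError(
                        f"block '{name}': bad token {tok!r}") from exc
    return np.asarray(vals)


def _default_paths() -> list:
    data = resources.files("rnaprof") / "data"
    return [data / "rna_turner2004.par", data / "rna_turner2004_int22.par"]


def load_parameters(source: Union[str, Path, Iterable] = "default",
                    temperature: float | None = None) -> EnergyParameters:
    """Load an energy parameter set.

    Parameters
    ----------
    source
        ``"default"`` for the bundled Turner 2004 tables, a path to a
        Vienna-dialect parameter file, or an iterable of such paths whose
        blocks are merged (later files override earlier ones).
    temperature
        Optional override of the absolute temperature in Kelvin.  A
        ``# Temperature`` block in the file has the same effect; the
        argument wins over the file.
    """
    if isinstance(source, (str, Path)) and str(source) == "default":
        paths = _default_paths()
    elif isinstance(source, (str, Path)):
        paths = [Path(source)]
    else:
        paths = [Path(p) for p in source]

    blocks: dict[str, list[str]] = {}
    for p in paths:
        try:
            text = p.read_text()
        except OSError as exc:
            raise ParameterError(f"cannot read parameter file {p}") from exc
        blocks.update(_tokenize(text))

    tables = {}
    for name, shape in _MATRIX_BLOCKS.items():
        want = int(np.prod(shape))
        if name not in blocks:
            tables[name] = np.zeros(shape)
            continue
        vals = _parse_numbers(name, blocks[name])
        if vals.size != want:
            raise ParameterError(
                f"block '{name}': expected {want} entries, got {vals.size}")
        tables[name] = vals.reshape(shape)

    ml = _parse_numbers("ML_params", blocks.get("ML_params", ["0 0 0 0 0 0"]))
    if ml.size < 5:
        raise ParameterError("block 'ML_params': expected >= 5 entries")
    # layout: unpaired, unpaired_dH, closing, closing_dH, branch, branch_dH
    ml_unpaired, ml_close, ml_branch = ml[0], ml[2], ml[4]

    ninio = _parse_numbers("NINIO", blocks.get("NINIO", ["0 0 0"]))
    if ninio.size != 3:
        raise ParameterError("block 'NINIO': expected 3 entries")

    misc = _parse_numbers("Misc", blocks.get("Misc", ["0 0 0 0"]))
    if misc.size < 3:
        raise ParameterError("block 'Misc': expected >= 3 entries")
    terminal_au = misc[2]

    special: dict[str, float] = {}
    for name in _SPECIAL_BLOCKS:
        for line in blocks.get(name, []):
            toks = [t for t in line.split() if t != "#END"]
            if not toks:
                continue
            if len(toks) < 2:
                raise ParameterError(f"block '{name}': bad line {line!r}")
            special[normalize(toks[0])] = float(toks[1]) / 100.0

    temp = DEFAULT_TEMPERATURE
    if "Temperature" in blocks:
        tvals = _parse_numbers("Temperature", blocks["Temperature"])
        if tvals.size != 1:
            raise ParameterError("block 'Temperature': expected 1 entry")
        temp = float(tvals[0]) * 100.0  # undo the /100 energy scaling
    if temperature is not None:
        temp = float(temperature)
    if temp <= 0:
        raise ParameterError("temperature must be positive")

    return EnergyParameters(
        stack=tables["stack"],
        hairpin_by_length=tables["hairpin"],
        hairpin_mismatch=tables["mismatch_hairpin"],
        bulge_by_length=tables["bulge"],
        internal_by_length=tables["internal"],
        internal_mismatch=tables["mismatch_internal"],
        internal_asymmetry=float(ninio[0]),
        internal_asymmetry_max=float(ninio[2]),
        int11=tables["int11"],
        int21=tables["int21"],
        int22=tables["int22"],
        multiloop_close=float(ml_close),
        multiloop_branch=float(ml_branch),
        multiloop_unpaired=float(ml_unpaired),
        terminal_au=float(terminal_au),
        special_hairpins=special,
        temperature_K=temp,
    )


def write_parameters(params: EnergyParameters, path: Union[str, Path]) -> None:
    """Serialize a parameter set back to the text dialect (round-trip safe)."""

    def fmt(x: float) -> str:
        if not np.isfinite(x):
            return "INF"
        return str(int(round(x * 100)))

    with open(path, "w") as fh:
        fh.write("## RNAfold parameter file v2.0\n")
        for name, attr in (("stack", "stack"),
                           ("mismatch_hairpin", "hairpin_mismatch"),
                           ("mismatch_internal", "internal_mismatch"),
                           ("int11", "int11"), ("int21", "int21"),
                           ("int22", "int22"),
                           ("hairpin", "hairpin_by_length"),
                           ("bulge", "bulge_by_length"),
                           ("internal", "internal_by_length")):
            vals = getattr(params, attr).ravel()
            fh.write(f"\n# {name}\n")
            for i in range(0, vals.size, 10):
                fh.write(" ".join(fmt(v) for v in vals[i:i + 10]) + "\n")
        fh.write("\n# ML_params\n")
        fh.write(" ".join(fmt(v) for v in (
            params.multiloop_unpaired, 0.0, params.multiloop_close, 0.0,
            params.multiloop_branch, 0.0)) + "\n")
        fh.write("\n# NINIO\n")
        fh.write(" ".join(fmt(v) for v in (
            params.internal_asymmetry, 0.0, params.internal_asymmetry_max))
            + "\n")
        fh.write("\n# Misc\n")
        fh.write(" ".join(fmt(v) for v in (0.0, 0.0, params.terminal_au, 0.0))
                 + "\n")
        for name, size in (("Triloops", 5), ("Tetraloops", 6),
                           ("Hexaloops", 8)):
            entries = {s: e for s, e in params.special_hairpins.items()
                       if len(s) == size}
            if entries:
                fh.write(f"\n# {name}\n")
                for s, e in entries.items():
                    fh.write(f"{s} {fmt(e)}\n")
        if params.temperature_K != DEFAULT_TEMPERATURE:
            fh.write(f"\n# Temperature\n{params.temperature_K}\n")


# ---------------------------------------------------------------------------
# Loop free energies
# ---------------------------------------------------------------------------

def _codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode(normalize(seq))
    return np.asarray(seq, dtype=np.int8)


def _pt(codes: np.ndarray, i: int, j: int) -> int:
    return int(PAIR_TYPE[codes[i], codes[j]])


def _term_au(pt: int, params: EnergyParameters) -> float:
    return params.terminal_au if pt >= 2 else 0.0


def _length_term(table: np.ndarray, L: int, lxc: float) -> float:
    if L <= 30:
        return float(table[L])
    return float(table[30]) + lxc * math.log(L / 30.0)


def hairpin_energy(seq, i: int, j: int, params: EnergyParameters) -> float:
    """Free energy of a hairpin loop closed by pair (i, j); 0-based indices."""
    codes = _codes(seq)
    if not (0 <= i < j < len(codes)):
        raise IndexError("hairpin indices out of range")
    pt = _pt(codes, i, j)
    L = j - i - 1
    if pt < 0 or L < 3:
        return _INF
    if 3 <= L <= 6 and params.special_hairpins:
        key = "".join("ACGUN"[c] for c in codes[i:j + 1])
        if key in params.special_hairpins:
            return params.special_hairpins[key]
    e = _length_term(params.hairpin_by_length, L, params.lxc)
    if L == 3:
        e += _term_au(pt, params)
    else:
        si, sj = codes[i + 1], codes[j - 1]
        e += float(params.hairpin_mismatch[pt,
                                           si + 1 if si < 4 else 0,
                                           sj + 1 if sj < 4 else 0])
    return e


def interior_energy(seq, i: int, j: int, p: int, q: int,
                    params: EnergyParameters,
                    loop_cap: int = DEFAULT_LOOP_CAP) -> float:
    """Free energy of the bulge/internal loop between pairs (i, j) and (p, q).

    Geometry violations (including a total unpaired length above
    ``loop_cap``) return ``+inf`` rather than raising, so callers can
    iterate freely over candidate inner pairs.
    """
    codes = _codes(seq)
    m, n = p - i - 1, j - q - 1
    if m < 0 or n < 0 or m + n == 0 or m + n > loop_cap or not i < p <= q < j:
        return _INF
    pt1 = _pt(codes, i, j)
    pt2 = _pt(codes, q, p)           # inner pair viewed from inside the loop
    if pt1 < 0 or pt2 < 0:
        return _INF
    L = m + n

    def b(k):  # table index of base code (N -> 0)
        c = int(codes[k])
        return c + 1 if c < 4 else 0

    if m == 0 or n == 0:              # bulge
        e = _length_term(params.bulge_by_length, L, params.lxc)
        if L == 1:
            e += float(params.stack[pt1, pt2])
        else:
            e += _term_au(pt1, params) + _term_au(pt2, params)
        return e
    if m == 1 and n == 1:
        return float(params.int11[pt1, pt2, b(i + 1), b(j - 1)])
    if m == 1 and n == 2:
        return float(params.int21[pt1, pt2, b(i + 1), b(q + 1), b(j - 1)])
    if m == 2 and n == 1:
        return float(params.int21[pt2, pt1, b(q + 1), b(i + 1), b(p - 1)])
    if m == 2 and n == 2 and all(codes[k] < 4 for k in
                                 (i + 1, p - 1, q + 1, j - 1)):
        return float(params.int22[pt1, pt2, codes[i + 1], codes[p - 1],
                                  codes[q + 1], codes[j - 1]])
    e = _length_term(params.internal_by_length, L, params.lxc)
    e += min(params.internal_asymmetry_max,
             abs(m - n) * params.internal_asymmetry)
    e += float(params.internal_mismatch[pt1, b(i + 1), b(j - 1)])
    e += float(params.internal_mismatch[pt2, b(q + 1), b(p - 1)])
    return e


def stack_energy(seq, i: int, j: int, params: EnergyParameters) -> float:
    """Stacking free energy of pair (i, j) on the adjacent pair (i+1, j-1)."""
    codes = _codes(seq)
    pt1 = _pt(codes, i, j)
    pt2 = _pt(codes, j - 1, i + 1)
    if pt1 < 0 or pt2 < 0 or j - 1 <= i + 1:
        return _INF
    return float(params.stack[pt1, pt2])


def multiloop_close_energy(seq, i: int, j: int,
                           params: EnergyParameters) -> float:
    """Closing pair (i, j) of a multibranch loop: a + b + terminal AU."""
    codes = _codes(seq)
    pt = _pt(codes, i, j)
    if pt < 0:
        return _INF
    return (params.multiloop_close + params.multiloop_branch
            + _term_au(pt, params))


def multiloop_branch_energy(seq, i: int, j: int,
                            params: EnergyParameters) -> float:
    """A helix branching off a multibranch loop: b + terminal AU."""
    codes = _codes(seq)
    pt = _pt(codes, i, j)
    if pt < 0:
        return _INF
    return params.multiloop_branch + _term_au(pt, params)


def multiloop_unpaired_energy(params: EnergyParameters) -> float:
    return params.multiloop_unpaired


def external_branch_energy(seq, i: int, j: int,
                           params: EnergyParameters) -> float:
    """A helix meeting the exterior loop pays only the terminal-AU penalty."""
    codes = _codes(seq)
    pt = _pt(codes, i, j)
    if pt < 0:
        return _INF
    return _term_au(pt, params)


# ---------------------------------------------------------------------------
# Boltzmann weights
# ---------------------------------------------------------------------------

def boltzmann_weight(delta_G: float, params: EnergyParameters) -> float:
    """``exp(-dG / RT)``; an infinite energy maps to weight 0."""
    if not np.isfinite(delta_G):
        return 0.0
    return math.exp(-delta_G / params.RT)


def _weight(fn):
    def wrapped(seq, *args):
        *idx, params = args
        return boltzmann_weight(fn(seq, *idx, params), params)
    wrapped.__name__ = fn.__name__.replace("_energy", "_weight")
    return wrapped


hairpin_weight = _weight(hairpin_energy)
stack_weight = _weight(stack_energy)
multiloop_close_weight = _weight(multiloop_close_energy)
multiloop_branch_weight = _weight(multiloop_branch_energy)
external_branch_weight = _weight(external_branch_energy)


def interior_weight(seq, i, j, p, q, params: EnergyParameters,
                    loop_cap: int = DEFAULT_LOOP_CAP) -> float:
    return boltzmann_weight(
        interior_energy(seq, i, j, p, q, params, loop_cap), params)


def multiloop_unpaired_weight(params: EnergyParameters) -> float:
    return boltzmann_weight(multiloop_unpaired_energy(params), params)
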