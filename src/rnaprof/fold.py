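"""Banded inside-outside dynamic program over the seven-state RNA grammar.

The grammar (states Outer, Stem, StemEnd, Multi, MultiBif, Multi1, Multi2)
generates every pseudoknot-free secondary structure exactly once, subject
to three structural constraints shared with the enumeration oracle:

* a base pair may span at most ``W`` bases (inclusive paired-region width);
* hairpin loops contain at least 3 unpaired bases;
* bulge/internal loops contain at most ``C`` unpaired bases in total.

Runtime is O(N W^2 + N W C^2) with O(N W) memory (banded tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._seq import PAIR_TYPE, encode, normalize
from .energy import (DEFAULT_LOOP_CAP, EnergyParameters, load_parameters)

__all__ = ["DPIndexing", "InsideTables", "OutsideTables", "inside",
           "outside", "partition_function", "log_partition_function",
           "operation_counts"]

STATES = ("Stem", "StemEnd", "Multi", "MultiBif", "Multi1", "Multi2")


@dataclass(frozen=True)
class DPIndexing:
    """Gap-coordinate bookkeeping for the banded tables.

    DP index ``k`` in ``0..N`` is the boundary before base ``k+1``; a state
    over ``(i, j]`` covers 1-based bases ``i+1..j`` and banded tables store
    entry ``(i, j)`` at ``[i, j - i]``.  ``Stem(i, j)`` assumes the pair
    ``(i+1, j)``.  Pairs are admissible when their paired region spans at
    most ``W`` bases, i.e. ``j - i <= W`` in gap coordinates, uniformly in
    every recursion including the exterior (Outer) attachments.
    """

    N: int
    W: int
    C: int = DEFAULT_LOOP_CAP


@dataclass
class InsideTables:
    """Inside variables: banded alpha tables plus the log-space Outer chain.

    ``alpha[s][i, d]`` is the inside weight of state ``s`` over span
    ``(i, i+d]`` rescaled by ``exp(eta * d)``; ``alpha_outer_log[i]`` is
    ``log`` of the unscaled Outer inside value.
    """

    indexing: DPIndexing
    eta: float
    alpha: dict
    alpha_outer_log: np.ndarray
    codes: np.ndarray = field(repr=False)
    params: EnergyParameters = field(repr=False)
    _tw: tuple = field(repr=False)


@dataclass
class OutsideTables:
    """Outside variables; banded betas are stored divided by Z and rescaled
    so that ``alpha[s] * beta[s]`` is directly a probability."""

    indexing: DPIndexing
    beta: dict
    beta_outer_log: np.ndarray


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode(normalize(seq))
    return np.ascontiguousarray(seq, dtype=np.int8)


def default_eta(W: int) -> float:
    """Per-base rescaling rate (nats/base) keeping banded weights in range."""
    if W <= 200:
        return 0.0
    return max(0.0, min(680.0 / W, 2.9 - 650.0 / W))


_TW_CACHE: dict = {}


def _weight_tables(params: EnergyParameters, Lmax: int, C: int, eta: float):
    key = (id(params), Lmax, C, round(eta, 9))
    hit = _TW_CACHE.get(key)
    if hit is not None:
        return hit
    RT = params.RT

    def wexp(E, shift=0.0):
        E = np.asarray(E, dtype=float)
        out = np.zeros_like(E)
        fin = np.isfinite(E)
        out[fin] = np.exp(-E[fin] / RT + shift)
        return out

    def extrapolate(table, n):
        full = np.empty(n + 1)
        full[:31] = table
        if n > 30:
            L = np.arange(31, n + 1)
            full[31:] = table[30] + params.lxc * np.log(L / 30.0)
        return full

    wterm = np.ones(7)
    wterm[2:6] = math.exp(-params.terminal_au / RT)
    west = wexp(params.stack)
    wstack = west * math.exp(-2.0 * eta)
    wse = math.exp(-2.0 * eta)
    hp_max = max(31, Lmax)
    hp = extrapolate(params.hairpin_by_length, hp_max)
    whp_len = wexp(hp) * np.exp(-eta * np.arange(hp_max + 1))
    wmmh = wexp(params.hairpin_mismatch)
    cap = max(31, C + 1) - 1
    wbul = wexp(extrapolate(params.bulge_by_length, cap)) \
        * np.exp(-eta * np.arange(cap + 1))
    wintl = wexp(extrapolate(params.internal_by_length, cap)) \
        * np.exp(-eta * np.arange(cap + 1))
    asym = np.minimum(params.internal_asymmetry_max,
                      np.arange(cap + 1) * params.internal_asymmetry)
    wasym = np.exp(-asym / RT)
    wmmi = wexp(params.internal_mismatch)
    wi11 = wexp(params.int11) * math.exp(-2.0 * eta)
    wi21 = wexp(params.int21) * math.exp(-3.0 * eta)
    wi22 = wexp(params.int22) * math.exp(-4.0 * eta)
    wml_close = wexp(np.full(7, params.multiloop_close
                             + params.multiloop_branch)) * wterm
    wml_branch = wexp(np.full(7, params.multiloop_branch)) * wterm
    wml_unp = math.exp(-params.multiloop_unpaired / RT - eta)
    wext = wterm.copy()

    skeys = []
    svals = []
    for s, E in params.special_hairpins.items():
        if any(ch not in "ACGU" for ch in s) or len(s) not in (5, 6, 8):
            continue
        L = len(s) - 2
        key2 = L
        for ch in s:
            key2 = key2 * 4 + "ACGU".index(ch)
        skeys.append(key2)
        svals.append(math.exp(-E / RT - eta * L))
    order = np.argsort(np.asarray(skeys, dtype=np.int64)) \
        if skeys else np.empty(0, dtype=np.int64)
    skeys_a = np.asarray(skeys, dtype=np.int64)[order]
    svals_a = np.asarray(svals, dtype=float)[order]

    tw = (wstack, wse, whp_len, wmmh, wterm, skeys_a, svals_a, wbul, wintl,
          wasym, wmmi, west, wi11, wi21, wi22, wml_close, wml_branch,
          wml_unp, wext)
    if len(_TW_CACHE) > 32:
        _TW_CACHE.clear()
    _TW_CACHE[key] = tw
    return tw


def _resolve(seq, params, W, loop_cap):
    codes = _as_codes(seq)
    N = codes.size
    if N < 1:
        raise ValueError("empty sequence")
    if W is None or W < 1:
        raise ValueError("maximal span W must be >= 1")
    W = min(int(W), N)
    if params is None:
        params = load_parameters("default")
    return codes, N, W, int(loop_cap), params


def inside(seq, params: EnergyParameters | None = None, W: int = None,
           loop_cap: int = DEFAULT_LOOP_CAP,
           eta: float | None = None) -> InsideTables:
    """Run the inside algorithm; returns banded alpha tables.

    ``seq`` may be a string (normalized automatically) or an int8 code
    array.  ``W`` is clamped to the sequence length.
    """
    codes, N, W, C, params = _resolve(seq, params, W, loop_cap)
    if eta is None:
        eta = default_eta(W)
    tw = _weight_tables(params, W, C, eta)
    aS, aSE, aM, aMB, aM1, aM2, la = _kernels.inside_kernel(
        codes, W, C, eta, PAIR_TYPE, tw)
    alpha = dict(zip(STATES, (aS, aSE, aM, aMB, aM1, aM2)))
    return InsideTables(DPIndexing(N, W, C), eta, alpha, la, codes, params,
                        tw)


def outside(seq, params: EnergyParameters | None = None, W: int = None,
            inside_tables: InsideTables = None) -> OutsideTables:
    """Run the outside algorithm for a previously computed inside pass."""
    if inside_tables is None:
        inside_tables = inside(seq, params, W)
    ix = inside_tables.indexing
    codes = inside_tables.codes
    if seq is not None:
        check = _as_codes(seq)
        if check.size != codes.size or not np.array_equal(check, codes):
            raise ValueError("sequence does not match the inside tables")
    a = inside_tables.alpha
    bS, bSE, bM, bMB, bM1, bM2, lb = _kernels.outside_kernel(
        codes, ix.W, ix.C, inside_tables.eta, PAIR_TYPE, inside_tables._tw,
        a["Stem"], a["Multi1"], a["Multi2"], inside_tables.alpha_outer_log)
    beta = dict(zip(STATES, (bS, bSE, bM, bMB, bM1, bM2)))
    return OutsideTables(ix, beta, lb)


def log_partition_function(inside_tables: InsideTables) -> float:
    return float(inside_tables.alpha_outer_log[-1])


def partition_function(inside_tables: InsideTables) -> float:
    """Z as a float (>= 1; the open chain contributes weight 1)."""
    return math.exp(log_partition_function(inside_tables))


def operation_counts(N: int, W: int, C: int = DEFAULT_LOOP_CAP) -> dict:
    """Closed-form inner-iteration counts of the banded recursions.

    Counts the innermost loop executions of one inside pass, one outside
    pass and the profile readout, mirroring the kernel loop bounds (without
    sequence-dependent sparsity short-cuts).  Used to verify the
    O(N W^2 + N W C^2) complexity contract by counting, not timing.
    """
    W = min(W, N)
    d = np.arange(W + 1)
    starts = np.maximum(N - d + 1, 0).astype(float)  # i-loop length per d

    bif = np.where(d >= 10, np.maximum(d - 9, 0), 0) * starts
    # interior (m, n) lattice per StemEnd span, capped by C
    Lmax = np.minimum(C, np.maximum(d - 5, -1))
    interior_per = np.where(Lmax >= 1, (Lmax + 1) * (Lmax + 2) / 2 - 1, 0)
    se_starts = np.where(d + 2 <= W, np.maximum(N - d - 1, 0),
                         0).astype(float)
    interior = interior_per * se_starts
    outer = float(np.minimum(np.arange(N + 1), W).sum())
    band = float(starts.sum())

    inside_ops = float(bif.sum() + interior.sum()) + outer + 5 * band
    outside_ops = float(2 * bif.sum() + 2 * interior.sum()) + outer + 5 * band
    readout_ops = float(interior.sum()) + 2 * outer + 2 * band
    total = inside_ops + outside_ops + readout_ops
    return {"inside": inside_ops, "outside": outside_ops,
            "readout": readout_ops, "total": total}
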