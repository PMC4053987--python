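import math

import numpy as np
import pytest

import rnaprof.energy as energy
import rnaprof.exact as exact
from rnaprof.fold import (inside, log_partition_function, operation_counts,
                          outside, partition_function)
from rnaprof.profile import compute_profile

from conftest import random_rna


def test_unpairable_sequence_has_unit_outer_chain(params):
    it = inside("AAAA", params, W=4)
    assert np.allclose(it.alpha_outer_log, 0.0)  # alpha_outer == 1
    for s, table in it.alpha.items():
        assert np.all(table == 0.0), s
    ot = outside("AAAA", inside_tables=it)
    assert np.allclose(ot.beta_outer_log, 0.0)
    assert partition_function(it) == 1.0


def test_w1_band_excludes_all_pairs(params):
    rng = np.random.default_rng(0)
    for _ in range(5):
        seq = random_rna(rng, 30)
        assert partition_function(inside(seq, params, W=1)) == 1.0


def test_beta_outer_boundary(params):
    ot = outside("GGGAAACCC", params, W=9)
    assert ot.beta_outer_log[-1] == 0.0  # beta_outer(N) = 1


def test_partition_function_matches_enumeration(params):
    seq = "GGGAAACCC"
    Z = partition_function(inside(seq, params, W=9))
    Zenum = sum(
        energy.boltzmann_weight(exact.structure_energy(seq, st, params),
                                params)
        for st in exact.enumerate_structures(seq, 9))
    assert Z == pytest.approx(Zenum, rel=1e-12)
    assert Z >= 1.0


def test_zero_energy_partition_function_counts_structures(zero_params):
    rng = np.random.default_rng(7)
    for _ in range(10):
        seq = random_rna(rng, int(rng.integers(6, 13)))
        Z = partition_function(inside(seq, zero_params, W=len(seq)))
        n = len(exact.enumerate_structures(seq))
        assert Z == pytest.approx(n, rel=1e-10)


def test_pair_probability_identity(params):
    """Sum over partners of the pair probability from the Stem tables
    equals p(i, S) from the profile readout."""
    rng = np.random.default_rng(1)
    seq = random_rna(rng, 60)
    W = 40
    it = inside(seq, params, W=W)
    ot = outside(None, inside_tables=it)
    aS, bS = it.alpha["Stem"], ot.beta["Stem"]
    N = it.indexing.N
    paired = np.zeros(N)
    for i in range(N + 1):
        for d in range(5, W + 1):
            if i + d > N:
                break
            P = aS[i, d] * bS[i, d]
            if P > 0:
                paired[i] += P          # 1-based position i+1
                paired[i + d - 1] += P  # 1-based position j
    prof = compute_profile(seq, params, W=W)
    assert np.abs(paired - prof["S"]).max() < 1e-9


def test_inside_outside_consistency(params):
    """alpha_s * beta_s is a probability: bounded by 1 (+ float slack)."""
    rng = np.random.default_rng(2)
    seq = random_rna(rng, 50)
    it = inside(seq, params, W=30)
    ot = outside(None, inside_tables=it)
    for s in it.alpha:
        prod = it.alpha[s] * ot.beta[s]
        assert prod.max() <= 1.0 + 1e-9, s


def test_numerical_stability_long_gc_rich(params):
    """No overflow/underflow on a long GC-rich sequence at large W."""
    rng = np.random.default_rng(3)
    seq = random_rna(rng, 1200, gc=0.7)
    prof = compute_profile(seq, params, W=600)
    assert np.isfinite(prof.probabilities).all()
    assert np.abs(prof.probabilities.sum(axis=1) - 1.0).max() < 1e-6
    it = inside(seq, params, W=600)
    assert np.isfinite(log_partition_function(it))


def test_w_clamped_to_sequence_length(params):
    a = compute_profile("GGGAAACCC", params, W=800).probabilities
    b = compute_profile("GGGAAACCC", params, W=9).probabilities
    assert np.allclose(a, b)


def test_operation_counts_match_explicit_iteration():
    """The closed-form counts equal a literal iteration over the kernel
    loop bounds."""
    N, W, C = 40, 20, 5
    bif = interior = 0
    for d in range(W + 1):
        for i in range(N - d + 1):
            j = i + d
            if d >= 10:
                bif += max(0, (j - 4) - (i + 5))  # k in range(i+5, j-4)
            if i >= 1 and j < N and d + 2 <= W and d >= 3:
                mmax = min(C, d - 5)
                for m in range(mmax + 1):
                    nmax = min(C - m, d - 5 - m)
                    nmin = 1 if m == 0 else 0
                    interior += max(0, nmax - nmin + 1)
    got = operation_counts(N, W, C)
    band = sum(N - d + 1 for d in range(W + 1))
    outer = sum(min(i, W) for i in range(N + 1))
    assert got["inside"] == bif + interior + outer + 5 * band
    assert got["outside"] == 2 * bif + 2 * interior + outer + 5 * band


def test_complexity_scaling_in_N():
    """Doubling N at fixed W about doubles the operation count."""
    r = operation_counts(4000, 200)["total"] / \
        operation_counts(2000, 200)["total"]
    assert 2 / 1.5 < r < 2 * 1.5
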