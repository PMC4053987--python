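import copy

import numpy as np
import pytest

from rnaprof import load_parameters
from rnaprof.profile import CONTEXTS
import rnaprof.exact as exact
import rnaprof.energy as energy


@pytest.fixture(scope="session")
def params():
    return load_parameters("default")


@pytest.fixture(scope="session")
def zero_params(params):
    """All finite energies set to zero: every admissible structure gets
    Boltzmann weight 1, so Z counts structures."""
    z = copy.deepcopy(params)
    for name in ("stack", "hairpin_by_length", "hairpin_mismatch",
                 "bulge_by_length", "internal_by_length",
                 "internal_mismatch", "int11", "int21", "int22"):
        arr = getattr(z, name)
        arr[...] = np.where(np.isfinite(arr), 0.0, arr)
    z.multiloop_close = z.multiloop_branch = z.multiloop_unpaired = 0.0
    z.terminal_au = 0.0
    z.internal_asymmetry = 0.0
    z.internal_asymmetry_max = 0.0
    z.lxc = 0.0
    z.special_hairpins = {}
    return z


def enumeration_profile(seq, params, W, loop_cap=30, max_len=22):
    """Independent expected profile: enumerate, weigh, classify, normalize."""
    structures = exact.enumerate_structures(seq, W, max_len=max_len)
    n = len(seq)
    acc = np.zeros((n, 6))
    z = 0.0
    col = {c: k for k, c in enumerate(CONTEXTS)}
    for st in structures:
        w = energy.boltzmann_weight(
            exact.structure_energy(seq, st, params, loop_cap), params)
        if w == 0.0:
            continue
        z += w
        for r, lab in enumerate(exact.classify_contexts(st)):
            acc[r, col[lab]] += w
    return acc / z


def random_rna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=n, p=p))
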