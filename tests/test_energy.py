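import math
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from importlib import resources

import rnaprof.energy as en
from rnaprof.energy import (EnergyParameters, ParameterError,
                            boltzmann_weight, external_branch_weight,
                            hairpin_energy, hairpin_weight, interior_energy,
                            interior_weight, load_parameters,
                            multiloop_unpaired_weight, stack_energy,
                            stack_weight, write_parameters)


def test_default_parameters_temperature(params):
    assert params.temperature_K == 310.15
    assert params.gas_constant == pytest.approx(1.98717e-3)
    assert params.RT == pytest.approx(0.6163207755)


def test_temperature_override_via_file(tmp_path, params):
    path = tmp_path / "override.par"
    write_parameters(params, path)
    text = path.read_text() + "\n# Temperature\n300\n"
    path.write_text(text)
    assert load_parameters(path).temperature_K == 300.0
    # explicit argument wins over the file
    assert load_parameters(path, temperature=320.0).temperature_K == 320.0


def test_stack_table_round_trips_bit_exactly_from_raw_file(params):
    """The first stack entry read through the parser equals the raw value
    in the bundled file (dcal/mol -> kcal/mol)."""
    raw = (resources.files("rnaprof") / "data" /
           "rna_turner2004.par").read_text()
    block = raw.split("# stack")[1].split("#")[0]
    first = float(block.split()[0])
    assert params.stack[0, 0] == first / 100.0


def test_malformed_parameter_file_names_block(tmp_path):
    bad = tmp_path / "bad.par"
    bad.write_text("## RNAfold parameter file v2.0\n# stack\n1 2 3\n")
    with pytest.raises(ParameterError, match="stack"):
        load_parameters(bad)
    with pytest.raises(ParameterError):
        load_parameters(tmp_path / "missing.par")


def test_parameter_round_trip(tmp_path, params):
    path = tmp_path / "roundtrip.par"
    write_parameters(params, path)
    assert load_parameters(path) == params


def test_boltzmann_weight_identities(params):
    assert boltzmann_weight(0.0, params) == 1.0
    assert boltzmann_weight(-params.RT * math.log(2), params) == \
        pytest.approx(2.0, rel=1e-12)
    # frozen scalar oracle: exp(-1 / (R*T)) at 310.15 K
    assert boltzmann_weight(1.0, params) == \
        pytest.approx(0.19739831122490537, rel=1e-12)
    assert boltzmann_weight(np.inf, params) == 0.0


@settings(max_examples=50, deadline=None)
@given(st.floats(-20, 20), st.floats(0.01, 5))
def test_boltzmann_weight_strictly_decreasing(dg, step):
    p = load_parameters("default")
    assert boltzmann_weight(dg + step, p) < boltzmann_weight(dg, p)


def test_hairpin_rejects_impossible_loops(params):
    assert hairpin_weight("GGAC", 0, 3, params) == 0.0    # loop of 2 (GC)
    assert hairpin_weight("AAAAA", 0, 4, params) == 0.0   # A-A not canonical
    with pytest.raises(IndexError):
        hairpin_weight("GAAAC", 0, 9, params)


def test_hairpin_energy_matches_manual_table_lookup(params):
    # GC-closed GAAA tetraloop, not in the special-loop table:
    # length term for 4 + terminal mismatch (pair GC, 5' G, 3' A)
    seq = "GGAAAC"
    pt = 1  # GC
    expected = params.hairpin_by_length[4] + \
        params.hairpin_mismatch[pt, 3, 1]  # G -> index 3, A -> index 1
    assert hairpin_energy(seq, 0, 5, params) == pytest.approx(expected)
    w = hairpin_weight(seq, 0, 5, params)
    assert w == pytest.approx(math.exp(-expected / params.RT))


def test_special_hairpin_replaces_generic_term(params):
    # CUUCGG is a tabulated tetraloop (closing C-G, loop UUCG)
    assert "CUUCGG" in params.special_hairpins
    assert hairpin_energy("CUUCGG", 0, 5, params) == \
        params.special_hairpins["CUUCGG"]


def test_interior_weight_geometry(params):
    seq = "GGCAGAAACAGCC"
    # m = n = 0 is a stack, not an interior loop
    assert interior_weight(seq, 2, 10, 3, 9, params) == 0.0
    # loop size above the cap vanishes instead of raising
    assert interior_weight("G" + "A" * 40 + "GAAAC" + "C", 0, 46, 41, 45,
                           params, loop_cap=30) == 0.0


def test_bulge_of_one_includes_stack_continuation(params):
    # structure (((...).)): outer pair (1,8)=C-G, inner (2,6)=G-C,
    # single bulged A on the 3' side
    seq = "GCGAAACAGC"
    e = interior_energy(seq, 1, 8, 2, 6, params)
    pt1 = 0   # CG outer
    pt2 = 0   # inner pair read from inside the loop: (C,G) -> CG
    expected = params.bulge_by_length[1] + params.stack[pt1, pt2]
    assert e == pytest.approx(expected)


def test_stack_weight_matches_table(params):
    # pair (0,3) = G-C over (1,2) = C-G; reversed inner (G,C) -> GC row
    seq = "GCGC"
    assert stack_energy(seq, 0, 3, params) == params.stack[1, 1]
    assert stack_weight(seq, 0, 3, params) == \
        pytest.approx(math.exp(-params.stack[1, 1] / params.RT))
    assert stack_weight("GAAC", 0, 3, params) == 0.0  # inner A-A


def test_terminal_au_scope(params):
    assert external_branch_weight("GAAAC", 0, 4, params) == 1.0
    w_au = external_branch_weight("AAAAU", 0, 4, params)
    assert w_au == pytest.approx(math.exp(-params.terminal_au / params.RT))


def test_multiloop_unpaired_weight_with_zero_coefficient(zero_params):
    assert multiloop_unpaired_weight(zero_params) == 1.0


@pytest.mark.parametrize("seq,db", [
    ("GGGAAACCC", "(((...)))"),                    # hairpin + stacks
    ("GCGAAACAGC", "(((...).))"),                  # bulge of 1
    ("GGCAAGAAACAAGCC", "(((..(...)..)))"),        # 2x2 internal loop
    ("GAAACGAAACGUCAAAGACAAAC", "(...((...))((...))....)"),  # multiloop
])
def test_structure_energy_matches_reference_implementation(seq, db, params):
    """Loop-energy attribution agrees with an independent implementation
    of the same published tables (RNAeval, no dangling ends)."""
    import subprocess

    from rnaprof.exact import SecondaryStructure, structure_energy
    out = subprocess.run(["RNAeval", "-d0"], input=f"{seq}\n{db}\n",
                         capture_output=True, text=True).stdout
    ref = float(out.splitlines()[1].rsplit("(", 1)[1].rstrip(") "))
    assert structure_energy(seq, SecondaryStructure(db), params) == \
        pytest.approx(ref, abs=5e-3)


def test_all_weights_nonnegative(params):
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(5, 15))
        seq = "".join(rng.choice(list("ACGUN"), size=n))
        i, j = 0, n - 1
        assert hairpin_weight(seq, i, j, params) >= 0.0
        assert stack_weight(seq, i, j, params) >= 0.0
        p = int(rng.integers(1, max(2, n - 2)))
        q = int(rng.integers(p, n - 1))
        assert interior_weight(seq, i, j, p, q, params) >= 0.0
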