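import numpy as np
import pytest

from rnaprof.clip import find_motif_sites
from rnaprof.simulate import (FixtureSpec, SimulationSpec, clip_fixture,
                              random_sequences, truncation_experiment,
                              w_sweep)


def test_random_sequences_gc_extremes():
    recs = random_sequences(SimulationSpec(2, 200, 1.0, seed=0))
    assert all(set(r.residues) <= {"G", "C"} for r in recs)
    recs = random_sequences(SimulationSpec(2, 200, 0.0, seed=0))
    assert all(set(r.residues) <= {"A", "U"} for r in recs)


def test_random_sequences_gc_within_binomial_bound():
    rec, = random_sequences(SimulationSpec(1, 100000, 0.5, seed=1))
    gc = sum(c in "GC" for c in rec.residues) / len(rec.residues)
    assert abs(gc - 0.5) < 3 * 0.5 / np.sqrt(100000)


def test_random_sequences_deterministic():
    a = random_sequences(SimulationSpec(3, 100, 0.4, seed=7))
    b = random_sequences(SimulationSpec(3, 100, 0.4, seed=7))
    assert [r.residues for r in a] == [r.residues for r in b]
    with pytest.raises(ValueError):
        random_sequences(SimulationSpec(1, 10, 1.5, seed=0))


def test_w_sweep_below_minimum_pairable_span(params):
    recs = random_sequences(SimulationSpec(3, 80, 0.5, seed=2))
    df = w_sweep(recs, [4], params)
    assert df.loc[4, "E"] == pytest.approx(1.0)
    assert np.all((df[list("BEHIMS")].to_numpy() >= 0)
                  & (df[list("BEHIMS")].to_numpy() <= 1))
    assert df[list("BEHIMS")].sum(axis=1).iloc[0] == pytest.approx(1.0)


def test_truncation_identity_when_nothing_truncated(params):
    # l covers the whole flank: truncated sequence == full sequence
    df = truncation_experiment(n_seqs=2, total_length=500, core=100,
                               l_values=[200], W=50, seed=3, params=params)
    assert np.allclose(df["pearson_r"], 1.0)
    with pytest.raises(ValueError):
        truncation_experiment(n_seqs=1, total_length=300, core=100,
                              l_values=[200], W=50, seed=0)


def test_fixture_peaks_match_truth_and_determinism():
    spec = FixtureSpec(n_transcripts=2, peaks_per_transcript=3,
                       transcript_length=3000, seed=11)
    recs, peaks, truth = clip_fixture(spec)
    bound = truth[truth["kind"] == "bound"]
    assert len(peaks) == len(bound)
    for p, (_, row) in zip(peaks, bound.iterrows()):
        assert (p.transcript_id, p.start, p.end) == \
            (row["transcript_id"], row["start"], row["end"])
    # every peak really contains a motif instance
    tx = {r.id: r.residues for r in recs}
    for p in peaks:
        assert find_motif_sites(tx[p.transcript_id], spec.motif, [p],
                                p.transcript_id)
    recs2, peaks2, truth2 = clip_fixture(spec)
    assert [r.residues for r in recs] == [r.residues for r in recs2]
    assert truth.equals(truth2)


def test_fixture_infeasible_plants_raise():
    with pytest.raises(ValueError):
        clip_fixture(FixtureSpec(motif="ACUK", planted_context="S",
                                 n_transcripts=1, peaks_per_transcript=1,
                                 transcript_length=2000, seed=0))
    with pytest.raises(ValueError):
        clip_fixture(FixtureSpec(motif="A" * 30, planted_context="I",
                                 n_transcripts=1, peaks_per_transcript=1,
                                 transcript_length=2000, seed=0))


def test_planted_hairpin_enriches_hairpin_context(params):
    """Motifs planted as hairpin loops show higher H than S probability
    at the motif positions (averaged over sites)."""
    from rnaprof.profile import compute_profile
    spec = FixtureSpec(planted_context="H", n_transcripts=1,
                       peaks_per_transcript=4, transcript_length=4000,
                       seed=21)
    recs, peaks, truth = clip_fixture(spec)
    tx = {r.id: r.residues for r in recs}
    h = s = 0.0
    for p in peaks:
        lo = max(0, p.start - 60)
        window = tx[p.transcript_id][lo:p.end + 60]
        prof = compute_profile(window, params, W=80)
        sl = slice(p.start - lo, p.end - lo)
        h += prof["H"][sl].mean()
        s += prof["S"][sl].mean()
    assert h / len(peaks) > 0.5
    assert h > s
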