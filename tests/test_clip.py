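from collections import Counter

import numpy as np
import pandas as pd
import pytest

from rnaprof.clip import (MotifSite, PeakRegion, PScoreTrack,
                          bonferroni_level, build_partial_shuffled_dataset,
                          build_shuffled_dataset, build_unbound_dataset,
                          combine_negatives, combine_tracks, dinuc_shuffle,
                          extract_positive_windows, find_all_matches,
                          find_motif_sites, iupac_regex, pscore, significant,
                          w_sensitivity, wmw_one_sided)


# ----------------------------------------------------------------- motifs

def test_iupac_matching():
    seq = "CCACUGCCACUUCC"
    peaks = [PeakRegion("t", 2, 12)]
    sites = find_motif_sites(seq, "ACUK", peaks, "t")
    assert sorted(s.start for s in sites) == [2, 8]  # ACUG and ACUU
    assert find_all_matches("CGGA", "WGGA") == []    # W = {A, U}
    with pytest.raises(ValueError):
        iupac_regex("ACZ")


def test_tiny_peak_slack_rule():
    # peak of length 1 at p; nearest match at p+10 kept, at p+11 dropped
    for offset, expect in [(10, 1), (11, 0)]:
        p = 20
        seq = "C" * (p + offset) + "ACUG" + "C" * 10
        sites = find_motif_sites(seq, "ACUK", [PeakRegion("t", p, p + 1)],
                                 "t")
        assert len(sites) == expect, offset


def test_peaks_without_match_dropped():
    seq = "CCCCCCCCCCCCCCCC"
    assert find_motif_sites(seq, "ACUK", [PeakRegion("t", 0, 16)], "t") == []


# ---------------------------------------------------------------- windows

def test_positive_window_arithmetic():
    seq = "A" * 10000
    site = MotifSite("t", 3000, 4, True, ("t", 3000, 3004))
    w, = extract_positive_windows({"t": seq}, [site], flank=2000)
    assert len(w.seq) == 4004 and w.motif_offset == 2000
    assert not w.truncated


def test_truncated_window_flagged():
    seq = "A" * 10000
    site = MotifSite("t", 100, 4, True, None)
    w, = extract_positive_windows({"t": seq}, [site], flank=2000)
    assert w.truncated and w.motif_offset == 100
    assert len(w.seq) == 100 + 4 + 2000


def test_unbound_radius_rules():
    # bound ACUG at 5000; candidate matches at 5400 (in), 6200 (out),
    # and one inside another peak (always excluded)
    seq = list("C" * 9000)
    for pos in (5000, 5400, 7500, 5600):
        seq[pos:pos + 4] = "ACUG"
    seq = "".join(seq)
    peaks = [PeakRegion("t", 5000, 5004), PeakRegion("t", 5600, 5604)]
    bound = find_motif_sites(seq, "ACUK", peaks, "t")
    assert sorted(s.start for s in bound) == [5000, 5600]
    wins = build_unbound_dataset({"t": seq}, "ACUK", bound, peaks,
                                 flank=100)
    starts = sorted(w.seq.index("ACUG") + 0 for w in wins)
    assert len(wins) == 1  # only the 5400 match
    distal = build_unbound_dataset({"t": seq}, "ACUK", bound, peaks,
                                   flank=100, rule="distal")
    assert len(distal) == 1  # only the 7500 match


# ---------------------------------------------------------------- shuffle

def test_dinuc_shuffle_preserves_counts():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(2, 80))
        s = "".join(rng.choice(list("ACGU"), size=n,
                               p=[0.4, 0.1, 0.2, 0.3]))
        sh = dinuc_shuffle(s, rng)
        assert Counter(zip(sh, sh[1:])) == Counter(zip(s, s[1:]))
        assert sh[0] == s[0] and sh[-1] == s[-1] and len(sh) == len(s)


def test_dinuc_shuffle_degenerate_inputs():
    rng = np.random.default_rng(1)
    assert dinuc_shuffle("ACG", rng) == "ACG"
    assert dinuc_shuffle("AAAAAA", rng) == "AAAAAA"
    assert dinuc_shuffle("A", rng) == "A"


def test_shuffled_datasets_keep_motif_and_core():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGU"), size=200))
    site = MotifSite("t", 100, 4, True, None)
    w, = extract_positive_windows({"t": seq}, [site], flank=80)
    full, = build_shuffled_dataset([w], np.random.default_rng(3))
    assert full.seq[w.motif_offset:w.motif_offset + 4] == \
        w.seq[w.motif_offset:w.motif_offset + 4]
    assert len(full.seq) == len(w.seq)
    part, = build_partial_shuffled_dataset([w], 5, np.random.default_rng(4))
    lo, hi = w.motif_offset - 5, w.motif_offset + 4 + 5
    assert part.seq[lo:hi] == w.seq[lo:hi]
    up, up0 = full.seq[:w.motif_offset], w.seq[:w.motif_offset]
    assert Counter(zip(up, up[1:])) == Counter(zip(up0, up0[1:]))


# ------------------------------------------------------------- statistics

def test_wmw_identical_samples():
    a = [1.0, 2.0, 3.0, 4.0]
    assert wmw_one_sided(a, a, "greater") >= 0.5
    assert wmw_one_sided(a, a, "less") >= 0.5


def test_wmw_exact_worked_example():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    assert wmw_one_sided(a, b, "less") == pytest.approx(0.05)
    assert wmw_one_sided(b, a, "greater") == pytest.approx(0.05)


def test_wmw_degenerate_sample_warns(caplog):
    assert wmw_one_sided([1.0], [2.0, 3.0]) == 1.0


def test_pscore_sign_convention():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    assert pscore(a, b) == pytest.approx(np.log10(0.05))   # negative
    assert pscore(b, a) == pytest.approx(-np.log10(0.05))  # positive
    same = [1.0, 2.0, 3.0, 4.0]
    assert abs(pscore(same, same)) <= np.log10(2.0) + 1e-12


@pytest.mark.parametrize("s1,s2,expected", [
    (3.0, 1.2, 1.2),
    (2.0, -1.0, 0.0),
    (-4.0, -2.5, -2.5),
    (-1.0, 2.0, 0.0),
    (0.0, 5.0, 0.0),
])
def test_combine_negatives(s1, s2, expected):
    assert combine_negatives(s1, s2) == expected


def test_bonferroni_level_and_significance():
    assert bonferroni_level(0.05, 1) == 0.05
    assert bonferroni_level(0.05, 250) == pytest.approx(2e-4)
    with pytest.raises(ValueError):
        bonferroni_level(0.05, 0)
    track = PScoreTrack(pd.DataFrame({"H": [1.0, 4.0]}), 0.05, 250)
    mask = significant(track)
    assert list(mask["H"]) == [False, True]  # threshold ~3.70


def _track(values):
    return PScoreTrack(pd.DataFrame({"H": values}), 0.05, len(values))


def test_combine_tracks_elementwise():
    t = combine_tracks(_track([3.0, 2.0, -4.0]), _track([1.2, -1.0, -2.5]))
    assert list(t.scores["H"]) == [1.2, 0.0, -2.5]


def test_w_sensitivity():
    assert w_sensitivity(_track([1.0, 2.0]), _track([1.0, 2.0]), "H") == 1.0
    assert w_sensitivity(_track([4.0]), _track([2.0]), "H") == 2.0
    assert np.isnan(w_sensitivity(_track([4.0]), _track([-1.0]), "H"))
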