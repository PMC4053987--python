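"""Structural-specificity statistics around protein-bound motif sites.

Given transcript sequences, CLIP-seq peak intervals (transcript
coordinates) and a sequential IUPAC motif, this module builds a positive
dataset of structural profiles around bound motif sites and two negative
datasets (transcribed-but-unbound motif sites, and dinucleotide-preserving
shuffles of the flanking sequence), then scores each position around the
motif with a signed P score: ``-log10`` of the smaller one-sided
Wilcoxon-Mann-Whitney p-value, negative when the context probability is
smaller in the positive set.  The two negative scores are combined
conservatively and thresholded at a Bonferroni-corrected level.

The analysis uses the contexts {B, H, I, S, U}: the unstructured track
U = E + M replaces the exterior and multibranch contexts because their
split depends strongly on the maximal span W while their union does not.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .energy import EnergyParameters
from .profile import compute_profile

__all__ = ["PeakRegion", "MotifSite", "ProfileDataset", "PScoreTrack",
           "IUPAC", "iupac_regex", "find_motif_sites",
           "extract_positive_windows", "build_unbound_dataset",
           "dinuc_shuffle", "build_shuffled_dataset",
           "build_partial_shuffled_dataset", "profile_windows",
           "wmw_one_sided", "pscore", "pscore_track", "combine_negatives",
           "combine_tracks", "bonferroni_level", "significant",
           "w_sensitivity", "run_clip_analysis"]

logger = logging.getLogger("rnaprof")

#: Contexts tested by the CLIP analysis (U = E + M).
CLIP_CONTEXTS = ("B", "H", "I", "S", "U")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

#: Default analysis parameters: profile span, window flank, peak-slack for
#: tiny peaks, unbound-site search radius, reporting flank around the motif.
DEFAULT_W = 200
DEFAULT_FLANK = 2000
PEAK_SLACK = 10
UNBOUND_RADIUS = 1000
REPORT_FLANK = 20


@dataclass(frozen=True)
class PeakRegion:
    """A CLIP peak in transcript coordinates (0-based, half-open)."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("peak requires 0 <= start < end")


@dataclass(frozen=True)
class MotifSite:
    """A motif occurrence on a transcript."""

    transcript_id: str
    start: int
    length: int
    bound: bool
    peak_key: tuple = None  # identifies the owning peak for bound sites


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif into a regex over {A, C, G, U}."""
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r} in motif")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def find_all_matches(seq: str, motif: str) -> list[int]:
    """Start positions of all (overlapping) motif matches."""
    pat = iupac_regex(motif)
    out = []
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            return out
        out.append(m.start())
        pos = m.start() + 1


def find_motif_sites(seq: str, motif: str, peaks: list,
                     transcript_id: str = "", slack: int = PEAK_SLACK
                     ) -> list[MotifSite]:
    """Bound sites: motif matches starting within a peak.

    Peaks spanning at most two bases are widened by ``slack`` nucleotides
    on both sides before matching.  Peaks without any match are dropped.
    """
    matches = find_all_matches(seq, motif)
    L = len(motif)
    sites = []
    for peak in peaks:
        if peak.transcript_id and transcript_id and \
                peak.transcript_id != transcript_id:
            continue
        lo, hi = peak.start, peak.end
        if hi - lo <= 2:
            lo, hi = max(0, lo - slack), hi + slack
        key = (peak.transcript_id, peak.start, peak.end)
        hits = [m for m in matches if lo <= m < hi]
        if not hits:
            logger.debug("peak %s has no motif match; dropped", key)
            continue
        for m in hits:
            sites.append(MotifSite(transcript_id or peak.transcript_id, m, L,
                                   True, key))
    return sites


@dataclass
class Window:
    """A sequence window centered on a motif site."""

    transcript_id: str
    seq: str
    motif_offset: int       # index of the motif start within ``seq``
    motif_len: int
    group: tuple            # observations sharing a group are averaged
    truncated: bool = False


def extract_positive_windows(transcripts: dict, sites: list,
                             flank: int = DEFAULT_FLANK) -> list[Window]:
    """Windows of motif +/- ``flank`` nt, truncated at transcript ends.

    Multiple bound sites in the same peak share a group and are later
    averaged into a single observation.
    """
    out = []
    for s in sites:
        seq = transcripts[s.transcript_id]
        lo = max(0, s.start - flank)
        hi = min(len(seq), s.start + s.length + flank)
        out.append(Window(
            s.transcript_id, seq[lo:hi], s.start - lo, s.length,
            group=s.peak_key if s.peak_key is not None
            else (s.transcript_id, s.start),
            truncated=(lo > s.start - flank
                       or hi < s.start + s.length + flank)))
    return out


def build_unbound_dataset(transcripts: dict, motif: str, bound_sites: list,
                          peaks: list, flank: int = DEFAULT_FLANK,
                          radius: int = UNBOUND_RADIUS,
                          rule: str = "within") -> list[Window]:
    """Windows around transcribed but unbound motif sites.

    ``rule="within"`` (the default) keeps unbound matches within
    ``radius`` nt of some bound site on the same transcript, i.e. sites
    that are certainly transcribed; ``rule="distal"`` keeps the
    complement (matches farther than ``radius`` from every bound site).
    """
    if rule not in ("within", "distal"):
        raise ValueError("rule must be 'within' or 'distal'")
    bound_by_tx: dict[str, list] = {}
    for s in bound_sites:
        bound_by_tx.setdefault(s.transcript_id, []).append(s.start)
    peak_iv: dict[str, list] = {}
    for p in peaks:
        peak_iv.setdefault(p.transcript_id, []).append((p.start, p.end))
    L = len(motif)
    out = []
    for tid, starts in bound_by_tx.items():
        seq = transcripts[tid]
        bound_set = set(starts)
        for m in find_all_matches(seq, motif):
            if m in bound_set:
                continue
            if any(lo <= m < hi for lo, hi in peak_iv.get(tid, ())):
                continue  # inside a peak: bound by definition
            near = any(abs(m - b) <= radius for b in starts)
            if (rule == "within") != near:
                continue
            site = MotifSite(tid, m, L, False)
            out.extend(extract_positive_windows({tid: seq}, [site], flank))
    return out


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffling (Euler-path construction)
# ---------------------------------------------------------------------------

def dinuc_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the multiset of overlapping dinucleotides.

    Altschul-Erickson construction: sample a uniform random arborescence
    toward the last character over the dinucleotide multigraph, then walk
    Euler trails with the remaining edges in random order.  First and last
    characters are always preserved.
    """
    n = len(seq)
    if n <= 3 or len(set(seq)) == 1:
        return seq
    letters = sorted(set(seq))
    edges: dict[str, list] = {c: [] for c in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # random arborescence rooted at `last`: backward random walk trick
    tree: dict[str, str] = {}
    for start in letters:
        if start == last:
            continue
        node = start
        path = []
        while node != last and node not in tree:
            nxt = edges[node][rng.integers(len(edges[node]))]
            path.append((node, nxt))
            node = nxt
        # loop-erased: keep the last exit of each node on the walk
        for a, b in path:
            tree[a] = b
    for c in letters:
        if c == last:
            rng.shuffle(edges[c])
            continue
        rest = list(edges[c])
        rest.remove(tree[c])
        rng.shuffle(rest)
        edges[c] = rest + [tree[c]]  # reserved tree edge leaves last
    out = [seq[0]]
    ptr = {c: 0 for c in letters}
    node = seq[0]
    for _ in range(n - 1):
        nxt = edges[node][ptr[node]]
        ptr[node] += 1
        out.append(nxt)
        node = nxt
    res = "".join(out)
    return res


def _shuffle_window(w: Window, keep: int, rng: np.random.Generator) -> Window:
    lo = max(0, w.motif_offset - keep)
    hi = min(len(w.seq), w.motif_offset + w.motif_len + keep)
    up = dinuc_shuffle(w.seq[:lo], rng)
    down = dinuc_shuffle(w.seq[hi:], rng)
    return Window(w.transcript_id, up + w.seq[lo:hi] + down, w.motif_offset,
                  w.motif_len, w.group, w.truncated)


def build_shuffled_dataset(windows: list, rng: np.random.Generator,
                           ) -> list[Window]:
    """Upstream and downstream flanks dinucleotide-shuffled independently;
    the motif itself is untouched."""
    return [_shuffle_window(w, 0, rng) for w in windows]


def build_partial_shuffled_dataset(windows: list, keep: int,
                                   rng: np.random.Generator) -> list[Window]:
    """Shuffle only outside motif +/- ``keep`` nucleotides."""
    return [_shuffle_window(w, keep, rng) for w in windows]


# ---------------------------------------------------------------------------
# Profile datasets and P scores
# ---------------------------------------------------------------------------

@dataclass
class ProfileDataset:
    """Observations x positions x contexts array of context probabilities.

    Positions are relative to the motif start over the reporting window
    ``-report_flank .. motif_len + report_flank - 1``.  Observations are
    peak-level averages of the windows sharing a group.
    """

    label: str
    data: np.ndarray
    rel_positions: np.ndarray
    contexts: tuple = CLIP_CONTEXTS
    motif_len: int = 0


def profile_windows(windows: list, label: str,
                    params: EnergyParameters | None = None,
                    W: int = DEFAULT_W,
                    report_flank: int = REPORT_FLANK) -> ProfileDataset:
    """Compute profiles for windows, slice the reporting region and
    average windows within each group into one observation."""
    if not windows:
        raise ValueError("no windows to profile")
    mlen = windows[0].motif_len
    rel = np.arange(-report_flank, mlen + report_flank)
    groups: dict[tuple, list] = {}
    for w in windows:
        if w.motif_offset + rel[0] < 0 or \
                w.motif_offset + rel[-1] >= len(w.seq):
            logger.warning("window too short for the reporting region; "
                           "skipped")
            continue
        prof = compute_profile(w.seq, params, W=W)
        P = prof.probabilities
        sl = slice(w.motif_offset + rel[0], w.motif_offset + rel[-1] + 1)
        # columns B,E,H,I,M,S -> B,H,I,S,U
        block = np.column_stack([
            P[sl, 0], P[sl, 2], P[sl, 3], P[sl, 5], P[sl, 1] + P[sl, 4]])
        groups.setdefault(w.group, []).append(block)
    if not groups:
        raise ValueError("no usable windows")
    data = np.stack([np.mean(blocks, axis=0) for blocks in groups.values()])
    return ProfileDataset(label, data, rel, CLIP_CONTEXTS, mlen)


def wmw_one_sided(a, b, direction: str = "greater") -> float:
    """One-sided Wilcoxon-Mann-Whitney p-value for H1: a <direction> b.

    Exact enumeration for small tie-free samples (both sizes <= 50),
    otherwise the normal approximation with tie and continuity
    corrections.  Degenerate samples (size < 2) give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if a.size < 2 or b.size < 2:
        logger.warning("sample of size < 2; p-value set to 1")
        return 1.0
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 50 and not ties) \
        else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative=direction,
                                    method=method).pvalue)


P_FLOOR = 1e-300


def pscore(positive, negative) -> float:
    """Signed P score comparing one position/context across datasets.

    ``-log10`` of the smaller one-sided WMW p-value; the sign is negative
    when the "positive smaller" hypothesis wins.  An exact tie between the
    two sides is given a positive sign.
    """
    p_greater = wmw_one_sided(positive, negative, "greater")
    p_less = wmw_one_sided(positive, negative, "less")
    if p_greater <= p_less:
        return -np.log10(max(p_greater, P_FLOOR))
    return np.log10(max(p_less, P_FLOOR))


@dataclass
class PScoreTrack:
    """Signed P scores per (relative position, context) with the
    Bonferroni-corrected significance level."""

    scores: pd.DataFrame      # index rel_position, columns contexts
    alpha: float
    n_tests: int

    @property
    def level(self) -> float:
        return bonferroni_level(self.alpha, self.n_tests)

    @property
    def threshold(self) -> float:
        """Score magnitude above which a position is significant."""
        return -np.log10(self.level)

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.stack().rename("score").reset_index()
        df.columns = ["rel_position", "context", "score"]
        df["significant"] = np.abs(df["score"].to_numpy()) > self.threshold
        return df


def pscore_track(positive: ProfileDataset, negative: ProfileDataset,
                 alpha: float = 0.05) -> PScoreTrack:
    """P scores at every reporting position for every analysis context."""
    if not np.array_equal(positive.rel_positions, negative.rel_positions):
        raise ValueError("datasets cover different reporting windows")
    rel = positive.rel_positions
    scores = np.empty((rel.size, len(positive.contexts)))
    for ci in range(len(positive.contexts)):
        for ri in range(rel.size):
            scores[ri, ci] = pscore(positive.data[:, ri, ci],
                                    negative.data[:, ri, ci])
    df = pd.DataFrame(scores, index=pd.Index(rel, name="rel_position"),
                      columns=list(positive.contexts))
    return PScoreTrack(df, alpha, rel.size * len(positive.contexts))


def combine_negatives(score_vs_unbound: float,
                      score_vs_shuffled: float) -> float:
    """Conservative combination of the scores against the two negatives.

    Matching signs: the score of smaller magnitude.  Opposite signs: 0.
    """
    s1, s2 = score_vs_unbound, score_vs_shuffled
    if s1 * s2 < 0:
        return 0.0
    return s1 if abs(s1) <= abs(s2) else s2


def combine_tracks(t1: PScoreTrack, t2: PScoreTrack) -> PScoreTrack:
    """Elementwise :func:`combine_negatives` of two tracks."""
    if not t1.scores.index.equals(t2.scores.index):
        raise ValueError("tracks cover different positions")
    a, b = t1.scores.to_numpy(), t2.scores.to_numpy()
    comb = np.where(a * b < 0, 0.0,
                    np.where(np.abs(a) <= np.abs(b), a, b))
    return PScoreTrack(pd.DataFrame(comb, index=t1.scores.index,
                                    columns=t1.scores.columns),
                       t1.alpha, t1.n_tests)


def bonferroni_level(alpha: float = 0.05, n_tests: int = 1) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def significant(track: PScoreTrack) -> pd.DataFrame:
    """Boolean mask of positions/contexts exceeding the corrected level."""
    return track.scores.abs() > track.threshold


def w_sensitivity(track_w400: PScoreTrack, track_w30: PScoreTrack,
                  context: str) -> float:
    """Ratio of the highest P score for a context at W=400 vs W=30.

    NaN when the denominator is not positive.
    """
    num = float(track_w400.scores[context].max())
    den = float(track_w30.scores[context].max())
    if den <= 0:
        return float("nan")
    return num / den


def run_clip_analysis(transcripts: dict, peaks: list, motif: str,
                      params: EnergyParameters | None = None,
                      flank: int = DEFAULT_FLANK, W: int = DEFAULT_W,
                      keep: int = 0, alpha: float = 0.05, seed: int = 0,
                      report_flank: int = REPORT_FLANK,
                      unbound_rule: str = "within",
                      max_unbound: int | None = None) -> dict:
    """End-to-end analysis: datasets, per-negative tracks, combined track.

    ``keep > 0`` replaces the fully shuffled negative by the partially
    shuffled one that keeps motif +/- ``keep`` nt intact.  ``max_unbound``
    caps the unbound dataset by a seeded random subsample (compute guard;
    unbound sites are often far more numerous than peaks).
    """
    rng = np.random.default_rng(seed)
    sites = []
    for tid, seq in transcripts.items():
        sites.extend(find_motif_sites(seq, motif,
                                      [p for p in peaks
                                       if p.transcript_id == tid],
                                      transcript_id=tid))
    if not sites:
        raise ValueError("no bound motif sites found")
    pos_windows = extract_positive_windows(transcripts, sites, flank)
    unb_windows = build_unbound_dataset(transcripts, motif, sites, peaks,
                                        flank, rule=unbound_rule)
    if max_unbound is not None and len(unb_windows) > max_unbound:
        keep_idx = rng.choice(len(unb_windows), size=max_unbound,
                              replace=False)
        unb_windows = [unb_windows[k] for k in sorted(keep_idx)]
    shuf_windows = (build_shuffled_dataset(pos_windows, rng) if keep == 0
                    else build_partial_shuffled_dataset(pos_windows, keep,
                                                        rng))
    pos = profile_windows(pos_windows, "positive", params, W, report_flank)
    shuf = profile_windows(shuf_windows, "shuffled", params, W, report_flank)
    t_shuf = pscore_track(pos, shuf, alpha)
    out = {"positive": pos, "shuffled": shuf, "track_vs_shuffled": t_shuf,
           "sites": sites}
    if unb_windows:
        unb = profile_windows(unb_windows, "unbound", params, W,
                              report_flank)
        t_unb = pscore_track(pos, unb, alpha)
        out.update({"unbound": unb, "track_vs_unbound": t_unb,
                    "combined": combine_tracks(t_unb, t_shuf)})
    else:
        logger.warning("no unbound motif sites; combined track equals the "
                       "shuffled-negative track")
        out["combined"] = t_shuf
    return out
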