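"""Synthetic inputs: random sequences, parameter sweeps, CLIP fixtures.

Everything here is a pure function of its specification (seed included):
the same spec yields byte-identical output.  Default problem sizes are
scaled down from the full-scale experiments (1,000 sequences of 2,000 nt)
so that complete analyses run in minutes; the full-scale settings remain
reachable through the arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clip import IUPAC, PeakRegion
from .energy import EnergyParameters
from .io import SequenceRecord
from .profile import CONTEXTS, compute_profile

__all__ = ["SimulationSpec", "random_sequences", "w_sweep", "gc_sweep",
           "truncation_experiment", "clip_fixture", "FixtureSpec"]

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


@dataclass(frozen=True)
class SimulationSpec:
    """Specification of a batch of random sequences."""

    n_sequences: int = 50
    length: int = 500
    gc_content: float = 0.5
    seed: int = 0


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=length, p=probs))


def random_sequences(spec: SimulationSpec) -> list[SequenceRecord]:
    """I.i.d. sequences with P(G) = P(C) = gc/2, P(A) = P(U) = (1-gc)/2."""
    if not 0.0 <= spec.gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    return [SequenceRecord(f"rand_{k + 1}", f"rand_{k + 1} gc="
                           f"{spec.gc_content} seed={spec.seed}",
                           _random_seq(rng, spec.length, spec.gc_content))
            for k in range(spec.n_sequences)]


def _mean_profile_row(records, W, params) -> dict:
    tot = np.zeros(6)
    n = 0
    for rec in records:
        P = compute_profile(rec.residues, params, W=W).probabilities
        tot += P.sum(axis=0)
        n += P.shape[0]
    row = {c: tot[k] / n for k, c in enumerate(CONTEXTS)}
    row["U"] = row["E"] + row["M"]
    return row


def w_sweep(records: list, W_values,
            params: EnergyParameters | None = None) -> pd.DataFrame:
    """Grand-mean context probabilities (over all bases of all sequences)
    per maximal span W."""
    rows = {W: _mean_profile_row(records, W, params) for W in W_values}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("W")


def gc_sweep(gc_values, W: int, n_sequences: int = 50, length: int = 500,
             seed: int = 0,
             params: EnergyParameters | None = None) -> pd.DataFrame:
    """Grand-mean context probabilities per GC content at fixed W."""
    rows = {}
    for gc in gc_values:
        recs = random_sequences(SimulationSpec(n_sequences, length, gc,
                                               seed))
        rows[gc] = _mean_profile_row(recs, W, params)
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gc")


def truncation_experiment(n_seqs: int = 5, total_length: int = 10100,
                          core: int = 100, l_values=(2000,), W: int = 100,
                          seed: int = 0,
                          params: EnergyParameters | None = None
                          ) -> pd.DataFrame:
    """Effect of flank truncation on the profile of a central core.

    For each random sequence, the profile of the central ``core`` bases is
    computed from the full sequence and from truncations keeping ``l``
    flanking nt on each side; the Pearson correlation between the two
    (pooled over core positions and the six contexts) is returned per
    (sequence, l).
    """
    if core + 2 * max(l_values) > total_length:
        raise ValueError("core + 2*max(l) exceeds the total length")
    rng = np.random.default_rng(seed)
    lo = (total_length - core) // 2
    hi = lo + core
    rows = []
    for k in range(n_seqs):
        seq = _random_seq(rng, total_length, 0.5)
        full = compute_profile(seq, params, W=W).probabilities[lo:hi]
        for l in l_values:
            sub = seq[lo - l:hi + l]
            trunc = compute_profile(sub, params, W=W).probabilities[l:l + core]
            r = np.corrcoef(full.ravel(), trunc.ravel())[0, 1]
            rows.append({"sequence": k + 1, "l": l, "pearson_r": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CLIP fixtures with motifs planted in chosen structural contexts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Specification of a synthetic CLIP fixture.

    Transcripts are random-background sequences with motif instances
    planted inside engineered structural cassettes; matching peak
    intervals mark the bound sites, and decoy motif instances planted
    outside peaks (but within the unbound-search radius of a bound site)
    feed the unbound negative dataset.
    """

    motif: str = "ACUK"
    planted_context: str = "H"   # one of H, U, S, I, B, or "neutral"
    n_transcripts: int = 6
    peaks_per_transcript: int = 5
    transcript_length: int = 6000
    spacing: int = 900           # distance between planted bound sites
    decoy_offset: int = 350      # decoy distance from its bound site
    stem_length: int = 10
    gc_content: float = 0.5
    seed: int = 0


def _sample_motif(motif: str, rng: np.random.Generator) -> str:
    out = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r} in motif")
        opts = IUPAC[ch]
        out.append(opts[rng.integers(len(opts))])
    return "".join(out)


def _stem(rng: np.random.Generator, length: int) -> str:
    # GC-biased helix arm so planted cassettes fold reliably
    return "".join(rng.choice(list("ACGU"), size=length,
                              p=[0.15, 0.35, 0.35, 0.15]))


def _cassette(context: str, motif: str, spec: FixtureSpec,
              rng: np.random.Generator) -> tuple[str, int]:
    """Build a planted cassette; returns (sequence, motif offset in it)."""
    sl = spec.stem_length
    if context == "H":
        loop = motif if len(motif) >= 3 else motif + "A" * (3 - len(motif))
        arm = _stem(rng, sl)
        return arm + loop + _revcomp(arm), sl
    if context == "U":
        au = lambda n: "".join(rng.choice(list("AU"), size=n))  # noqa: E731
        return au(15) + motif + au(15), 15
    if context == "S":
        if any(ch not in "ACGU" for ch in motif):
            raise ValueError("cannot plant an ambiguous motif as a helix")
        pad = _stem(rng, max(0, 6 - len(motif)))
        arm = motif + pad
        return arm + "GAAA" + _revcomp(arm), 0
    if context in ("I", "B"):
        if len(motif) > 28:
            raise ValueError("motif too long for an internal/bulge loop")
        outer, inner = _stem(rng, sl), _stem(rng, sl)
        hairpin = inner + "GAAA" + _revcomp(inner)
        other = "" if context == "B" else "".join(
            rng.choice(list("ACU"), size=2))
        return (outer + motif + hairpin + other + _revcomp(outer),
                sl)
    if context == "neutral":
        return motif, 0
    raise ValueError(f"cannot plant motif in context {context!r}")


def clip_fixture(spec: FixtureSpec) -> tuple[list, list, pd.DataFrame]:
    """Generate (transcripts, peaks, truth table) for a planted fixture.

    Every bound site is a motif instance inside a cassette engineered for
    the requested structural context; the peak interval equals the motif
    coordinates.  One decoy motif instance is planted ``decoy_offset`` nt
    downstream of each bound site, outside any peak, to populate the
    unbound dataset.
    """
    if spec.planted_context == "S" and any(
            len(IUPAC.get(ch, "")) != 1 for ch in spec.motif.upper()):
        raise ValueError(
            "planting in the stem context requires a non-degenerate motif "
            "(the motif itself forms one helix arm)")
    rng = np.random.default_rng(spec.seed)
    records = []
    peaks = []
    truth_rows = []
    margin = 400
    for t in range(spec.n_transcripts):
        tid = f"tx_{t + 1}"
        seq = list(_random_seq(rng, spec.transcript_length, spec.gc_content))
        pos = margin
        for k in range(spec.peaks_per_transcript):
            if pos + spec.spacing > spec.transcript_length - margin:
                break
            motif = _sample_motif(spec.motif, rng)
            cass, off = _cassette(spec.planted_context, motif, spec, rng)
            start = pos + int(rng.integers(0, 100))
            seq[start:start + len(cass)] = list(cass)
            mstart = start + off
            peaks.append(PeakRegion(tid, mstart, mstart + len(motif)))
            truth_rows.append({"transcript_id": tid, "start": mstart,
                               "end": mstart + len(motif),
                               "context": spec.planted_context,
                               "kind": "bound"})
            dstart = start + len(cass) + spec.decoy_offset
            dmotif = _sample_motif(spec.motif, rng)
            seq[dstart:dstart + len(dmotif)] = list(dmotif)
            truth_rows.append({"transcript_id": tid, "start": dstart,
                               "end": dstart + len(dmotif),
                               "context": "neutral", "kind": "decoy"})
            pos += spec.spacing
        records.append(SequenceRecord(tid, f"{tid} planted="
                                      f"{spec.planted_context}",
                                      "".join(seq)))
    return records, peaks, pd.DataFrame(truth_rows)
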