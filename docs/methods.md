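# Methods

## The model

`rnaprof` computes, for each base *i* of an RNA sequence *x*, the
probability that *i* lies in each of six secondary-structure contexts:
stem (S, paired), hairpin loop (H), bulge loop (B), internal loop (I),
multibranch loop (M) and exterior loop (E).  Contexts follow the loop
decomposition of pseudoknot-free secondary structures: viewing a
structure as a planar graph of backbone and hydrogen-bond edges, an
unpaired base that closes no polygon is exterior; a polygon with one
hydrogen bond is a hairpin loop; with two bonds it is a bulge when the
bonds are joined by a single backbone edge on one side and internal
otherwise; with more than two bonds it is a multibranch loop.  Every base
of every structure has exactly one context, so the six probabilities of a
base sum to 1.  The *structural profile* is this N x 6 matrix, together
with the derived unstructured track U = E + M.

Structures are weighted by the Boltzmann distribution of the
nearest-neighbor (Turner) free-energy model,

    p(i, c) = 1/Z * sum over structures where i has context c
              of exp(-dG(structure) / RT),
    Z       = sum over all structures of exp(-dG / RT),

with T = 310.15 K and dG measured relative to the open chain (the open
chain therefore contributes weight 1, so Z >= 1).  Three structural
constraints bound the ensemble:

* **maximal span W** — a pair is admissible only when its paired region
  covers at most W bases.  W is a required user parameter: profiles
  depend on it, and forcing an explicit choice prevents silent misuse;
* **minimum hairpin loop** of 3 unpaired bases;
* **loop cap C** (default 30) — maximal total unpaired length of a
  bulge/internal loop, the standard folding-tool convention.

## Grammar and dynamic program

The ensemble is generated exactly once per structure by an unambiguous
grammar with seven states (Outer, Stem, StemEnd, Multi, MultiBif, Multi1,
Multi2).  Outer emits exterior bases and attaches stems; Stem emits
pairs; StemEnd closes a helix with a hairpin, a bulge/internal loop, or a
multibranch loop; Multi/Multi1/Multi2/MultiBif decompose a multibranch
loop into two-or-more branch segments with unpaired spacers.  Inside and
outside passes over banded tables (gap coordinates, band j - i <= W)
yield all state posteriors in O(N W^2 + N W C^2) time and O(N W) memory.
Per-base context probabilities are then read out from inside x outside
products: E from the Outer chain, S from pair posteriors decomposed over
the closing transition, H/B/I from the loop-closing StemEnd states
(accumulated over the unpaired ranges with difference arrays), and M from
the two unpaired-emission transitions of the multibranch states.

Lonely (isolated) pairs are allowed — the grammar places no minimum on
helix length.  Ambiguous bases (N) are treated as unpairable but present:
they can occupy any loop context, which keeps Z finite and profiles
defined on real transcripts.

### Energy attribution

The bundled parameter set is the published Turner 2004 free energies at
37 C in the standard Vienna text dialect (`src/rnaprof/data/`, split into
a core file and the 2x2-loop table).  Conventions, applied identically by
the dynamic program and the enumeration oracle:

* hairpins: length term (log-extrapolated beyond 30) + terminal mismatch
  for loops > 3; loops of exactly 3 pay the terminal-AU penalty instead;
  tabulated special tri-/tetra-/hexaloops replace the whole term;
* bulges: length term; a bulge of 1 also stacks its flanking pairs,
  longer bulges pay terminal-AU at both helix ends;
* internal loops: tabulated 1x1, 1x2, 2x2 values; otherwise length +
  capped Ninio asymmetry + one terminal mismatch per side (the dedicated
  1xn and 2x3 mismatch variants are folded into the generic internal
  mismatch table — a deliberate simplification that keeps the parameter
  bundle small and both implementations in lockstep);
* multibranch loops: affine a + b per branch + c per unpaired base, with
  terminal-AU per non-GC helix end;
* exterior loops: unpaired bases free; terminal-AU per helix end;
* no dangling ends or coaxial stacking: the grammar emits no dangle
  states, and keeping energies strictly loop-local keeps the dynamic
  program exact with respect to the model it defines.

These conventions were cross-checked against an independent
implementation of the same published tables (`RNAeval -d0`) on hairpins,
bulges, 1x1/2x1/2x2/3x3 internal loops, multibranch and exterior loops,
with exact agreement.

### Numerical scheme

Boltzmann weights grow like exp(c N), so linear-space tables overflow on
long sequences.  Every transition weight is pre-multiplied by
s^-(bases emitted) with log s = eta chosen from W (0 for W <= 200), so
banded entries carry at most exp(O(W)) dynamic range; the Outer chains
are kept in log space, which absorbs the exp(O(N)) growth exactly.
Banded outside tables are stored divided by Z, making every inside x
outside product a probability directly.  If a pathological input still
overflows the band, the profile computation retries with a larger eta
(detected by non-finite entries, at most three retries).  Readout rows
are not renormalized; tiny negative values from difference-array
cancellation (magnitude < 1e-9) are clipped to zero.

### The W convention

"Span" is defined as the width of the paired region: a pair (i, j) in
1-based coordinates is admissible when j - i + 1 <= W, equivalently
j - i <= W in the gap coordinates of the banded tables — uniformly in
every recursion, including the attachment of stems to the exterior
chain.  With this convention W = 1 admits no pairs and W >= N admits all.
The enumeration oracle applies the identical rule, and the equivalence
suite pins the two implementations against each other to 1e-9.

## The enumeration oracle

`rnaprof.exact` recomputes profiles from first principles at desk scale:
it enumerates every admissible structure of a short sequence (first-
position recursion, guarded to N <= 16), classifies each base by the
polygon definitions, scores structures by an independent loop
decomposition (sharing only the per-loop energy functions with the
dynamic program, never the recursions), and normalizes.  The oracle is
deliberately simple and exponential; its only purpose is ground truth.
The acceptance suite checks the dynamic program against it exhaustively
for all sequences up to length 8 and for hundreds of longer random
sequences, at several W and loop-cap values, to 1e-9.

## CLIP-seq structural statistics

Given transcripts, peak intervals (transcript coordinates) and an IUPAC
motif:

* **bound sites** are motif matches starting inside a peak; peaks of <= 2
  bases are widened by +/-10 nt before matching; peaks without a match
  are dropped;
* the **positive dataset** collects windows of motif +/- 2,000 nt
  (truncated at transcript ends, flagged); profiles are computed at
  W = 200, sliced to a reporting window of +/-20 nt around the motif,
  and windows of the same peak are averaged into one observation;
* the **unbound negative** consists of motif matches on the same
  transcript that are not in any peak but lie within +/-1,000 nt of a
  bound site (so they are certainly transcribed).  The complementary
  "distal" reading is available behind a flag for sensitivity analysis.
  Because accidental matches typically outnumber peaks several-fold, a
  seeded subsample cap (`max_unbound`) bounds the computation;
* the **shuffled negative** dinucleotide-shuffles the two flanks of each
  positive window independently (Altschul-Erickson Euler-path
  construction; the motif, window length and dinucleotide counts are
  invariant).  Partially shuffled variants keep motif +/- 5 or 10 nt
  intact;
* the analysis uses contexts {B, H, I, S, U}: the E/M split depends
  strongly on W while U = E + M does not, so U replaces the two.

At each reporting position and context, a one-sided Wilcoxon-Mann-Whitney
test is run in both directions (exact enumeration when both samples have
<= 50 tie-free observations, otherwise the normal approximation with tie
and continuity corrections).  The **P score** is -log10 of the smaller
p-value (floored at 1e-300), sign-flipped when the "positive smaller"
side wins; an exact tie keeps the positive sign.  Scores against the two
negatives are combined conservatively: matching signs keep the smaller
magnitude, opposite signs give 0.  Significance uses a Bonferroni level
of alpha / (reporting positions x 5 contexts) per run — the most
defensible family definition, and configurable.  The W-sensitivity of a
context is the ratio of its highest P score at W = 400 vs W = 30.

## Synthetic data

The generators are pure functions of their specification (seed included).
Random sequences draw bases i.i.d. with P(G) = P(C) = gc/2.  The CLIP
fixture plants motif instances inside engineered cassettes on random
background transcripts (defaults: GC 0.5, ~6,000 nt): hairpin plants put
the motif in the loop of a 10-bp stem-loop; unstructured plants embed it
in an AU-only stretch; stem plants pair the motif against its reverse
complement; internal/bulge plants put it in the loop between two designed
helices.  Peaks equal the motif coordinates, and one decoy motif instance
is planted near each site (outside peaks) to feed the unbound dataset.
The fixture emulates motif-anchored binding sites with known structural
context; it does not emulate read-level noise, peak-calling uncertainty,
isoform structure or biased genomic composition, so passing tests
demonstrate correct recovery of planted structural signal, not
performance on real CLIP libraries.

## Problem sizes and defaults

Scaled-down defaults keep complete analyses in the minutes range while
preserving the experimental design; full-scale settings are plain
arguments:

* sweeps: 20–50 sequences of 500 nt (full scale: 1,000 x 2,000 nt);
* truncation experiment: 5 sequences of 10,100 nt, central 100 bases,
  l = 2,000, W = 100 (full scale: 100 sequences, l = 250..2,500).  The
  W for this experiment is a free choice; 100 is the package default and
  configurable;
* planted-fixture analyses: flanks of 60–150 nt and W = 60–150, enough
  to contain the engineered cassettes with margin;
* the truncation-experiment Pearson correlation pools core positions and
  all six contexts (per-context correlation is available from the same
  table).

## Known limitations

* No pseudoknots, G-quadruplexes, coaxial stacking or dangling ends; no
  temperature-dependent enthalpy rescaling (a temperature override only
  rescales RT).
* Numerical stability is engineered for realistic sequences up to
  N ~ 10,000 and W ~ 800; adversarial inputs (e.g. kilobase perfect GC
  helices) may exhaust the retry ladder and raise rather than return
  wrong numbers.
* Genome-to-transcript coordinate mapping, peak calling and transcript
  model construction are out of scope: the CLIP pipeline consumes
  caller-provided transcript sequences and transcript-relative peaks.
* The exact output layout of other profile tools is approximated by the
  `capr` writer on a best-effort basis.
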