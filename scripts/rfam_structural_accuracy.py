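#!/usr/bin/env python
"""Optional: structural-profile accuracy against annotated structures.

Given a local copy of an Rfam-style seed alignment file (Stockholm format
with an SS_cons line; not bundled, not downloaded here), computes per-
context AUROC values of the structural profiles against the annotated
contexts.  This reproduces the published benchmark protocol at full scale
and therefore requires the external dataset; it is provided as a
convenience and is not exercised by the test suite.

Usage:
    python scripts/rfam_structural_accuracy.py SEED.stk --max-span 800
"""

from __future__ import annotations

import argparse
from collections import defaultdict

import numpy as np

from rnaprof import compute_profile, load_parameters
from rnaprof.exact import SecondaryStructure, classify_contexts
from rnaprof.profile import CONTEXTS


def parse_stockholm(path):
    """Yield (family, {name: aligned_seq}, SS_cons) per alignment."""
    seqs: dict[str, str] = defaultdict(str)
    ss = ""
    fam = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith("#=GF AC"):
                fam = line.split()[-1]
            elif line.startswith("#=GC SS_cons"):
                ss += line.split()[-1]
            elif line and not line.startswith(("#", "//")):
                name, part = line.split()
                seqs[name] += part
            elif line.startswith("//"):
                yield fam, dict(seqs), ss
                seqs, ss, fam = defaultdict(str), "", ""


def wuss_to_dotbracket(ss: str) -> str:
    out = []
    for ch in ss:
        if ch in "<([{":
            out.append("(")
        elif ch in ">)]}":
            out.append(")")
        else:
            out.append(".")
    return "".join(out)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("seed", help="Stockholm seed alignment file")
    ap.add_argument("--max-span", type=int, default=800)
    ap.add_argument("--max-gap-fraction", type=float, default=0.5)
    args = ap.parse_args()
    params = load_parameters("default")

    scores: dict[str, list] = {c: [] for c in CONTEXTS}
    labels: dict[str, list] = {c: [] for c in CONTEXTS}
    for fam, seqs, ss in parse_stockholm(args.seed):
        if not ss or not seqs:
            continue
        cols = np.array(list(zip(*seqs.values())))
        gap_frac = np.mean(np.isin(cols, list(".-~")), axis=1)
        keep = gap_frac < args.max_gap_fraction
        db = "".join(np.array(list(wuss_to_dotbracket(ss)))[keep])
        # drop pairs broken by column filtering
        depth, fixed = 0, list(db)
        stack = []
        for k, ch in enumerate(fixed):
            if ch == "(":
                stack.append(k)
            elif ch == ")":
                if stack:
                    stack.pop()
                else:
                    fixed[k] = "."
        for k in stack:
            fixed[k] = "."
        contexts = classify_contexts(SecondaryStructure("".join(fixed)))
        for name, aligned in seqs.items():
            res = np.array(list(aligned))[keep]
            ungap = ~np.isin(res, list(".-~"))
            seq = "".join(res[ungap])
            if len(seq) < 10:
                continue
            ann = np.array(list(contexts))[ungap]
            prof = compute_profile(seq, params, W=args.max_span)
            for ci, c in enumerate(CONTEXTS):
                scores[c].extend(prof.probabilities[:, ci])
                labels[c].extend(ann == c)

    from sklearn.metrics import roc_auc_score
    for c in CONTEXTS:
        y = np.asarray(labels[c])
        if y.any() and not y.all():
            print(f"{c}\tAUROC = {roc_auc_score(y, scores[c]):.3f}")


if __name__ == "__main__":
    main()
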