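"""FASTA input and structural-profile serialization."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Union

import numpy as np
from Bio import SeqIO

from ._seq import count_unknown, normalize
from .profile import CONTEXTS, StructuralProfile

__all__ = ["SequenceRecord", "read_fasta", "write_profile", "read_profile"]

logger = logging.getLogger("rnaprof")

#: Long context names used by the original-tool-style ("capr") output.
_LONG = {"B": "Bulge", "E": "Exterior", "H": "Hairpin", "I": "Internal",
         "M": "Multibranch", "S": "Stem"}


@dataclass
class SequenceRecord:
    """One FASTA record with residues normalized to {A, C, G, U, N}."""

    id: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: Union[str, Path]) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file.

    Residues are uppercased, T is read as U and anything outside the
    alphabet becomes N (with a logged warning count).  Duplicate ids are
    suffixed ``_2``, ``_3``, ... deterministically.  Raises ``ValueError``
    for an empty file or a record with an empty sequence.
    """
    seen: dict[str, int] = {}
    n_records = 0
    unknown = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        unknown += count_unknown(raw)
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            rid = f"{rid}_{seen[rec.id]}"
            logger.warning("duplicate record id %r renamed to %r",
                           rec.id, rid)
        else:
            seen[rid] = 1
        yield SequenceRecord(rid, rec.description, normalize(raw))
    if n_records == 0:
        raise ValueError(f"no FASTA records found in {path}")
    if unknown:
        logger.warning("%d residues outside {A,C,G,T,U,N} were read as N",
                       unknown)


def write_profile(profile: StructuralProfile, path, format: str = "tsv",
                  append: bool = False) -> None:
    """Serialize a profile.

    ``tsv``: header ``position base B E H I M S U`` and one row per base
    with probabilities at 6 decimals.  ``capr``: a ``>name`` line followed
    by one line per context (Bulge, Exterior, Hairpin, Internal,
    Multibranch, Stem), mimicking the original tool's layout.
    """
    if format not in ("tsv", "capr"):
        raise ValueError(f"unknown profile format {format!r}")
    handle = open(path, "a" if append else "w") \
        if isinstance(path, (str, Path)) else path
    close = isinstance(path, (str, Path))
    try:
        P = profile.probabilities
        if format == "tsv":
            handle.write("# " + profile.name + "\n")
            handle.write("position\tbase\t" + "\t".join(CONTEXTS) + "\tU\n")
            U = profile.unstructured
            for r, base in enumerate(profile.sequence):
                vals = "\t".join(f"{v:.6f}" for v in P[r])
                handle.write(f"{r + 1}\t{base}\t{vals}\t{U[r]:.6f}\n")
        else:
            handle.write(">" + profile.name + "\n")
            for c, ctx in enumerate(CONTEXTS):
                vals = " ".join(f"{v:.6f}" for v in P[:, c])
                handle.write(f"{_LONG[ctx]} {vals}\n")
    finally:
        if close:
            handle.close()


def read_profile(path) -> list[StructuralProfile]:
    """Read profiles back from the ``tsv`` layout (round-trip of
    :func:`write_profile`)."""
    out = []
    name = "seq"
    rows: list[list[float]] = []
    seq: list[str] = []

    def flush():
        nonlocal rows, seq
        if rows:
            out.append(StructuralProfile(
                name, "".join(seq), np.asarray(rows), max_span=0))
        rows, seq = [], []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# "):
                flush()
                name = line[2:]
            elif line.startswith("position"):
                continue
            else:
                parts = line.split("\t")
                seq.append(parts[1])
                rows.append([float(x) for x in parts[2:8]])
    flush()
    return out
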