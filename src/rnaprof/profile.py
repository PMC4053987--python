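"""Per-base structural profiles: the six context probabilities.

For every base ``i`` of an RNA sequence the structural profile gives the
Boltzmann probability that ``i`` lies in each secondary-structure context:
bulge loop (B), exterior loop (E), hairpin loop (H), internal loop (I),
multibranch loop (M) and stem (S).  Rows sum to 1; the derived
"unstructured" track U = E + M is the probability of lying in a loop that
is not enclosed between two specific helices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels, fold
from ._seq import PAIR_TYPE, normalize
from .energy import DEFAULT_LOOP_CAP, EnergyParameters

__all__ = ["CONTEXTS", "StructuralProfile", "compute_profile",
           "unstructured_track"]

#: Fixed column order of the probability matrix.
CONTEXTS = ("B", "E", "H", "I", "M", "S")


@dataclass
class StructuralProfile:
    """N x 6 matrix of context probabilities for one sequence.

    ``probabilities[r, c]`` is the probability that 1-based position
    ``r + 1`` has context ``CONTEXTS[c]``.  Rows are not renormalized;
    they sum to 1 up to floating-point error.
    """

    name: str
    sequence: str
    probabilities: np.ndarray
    max_span: int

    def __len__(self) -> int:
        return len(self.sequence)

    def __getitem__(self, context: str) -> np.ndarray:
        if context == "U":
            return self.unstructured
        return self.probabilities[:, CONTEXTS.index(context)]

    @property
    def unstructured(self) -> np.ndarray:
        """U(i) = p(i, E) + p(i, M)."""
        return self.probabilities[:, 1] + self.probabilities[:, 4]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with 1-based positions, base identity and U column."""
        df = pd.DataFrame(self.probabilities, columns=list(CONTEXTS))
        df.insert(0, "base", list(self.sequence))
        df.insert(0, "position", np.arange(1, len(self.sequence) + 1))
        df["U"] = self.unstructured
        return df


def compute_profile(seq, params: EnergyParameters | None = None,
                    W: int = None, loop_cap: int = DEFAULT_LOOP_CAP,
                    name: str = "seq") -> StructuralProfile:
    """Compute the structural profile of one sequence.

    Parameters
    ----------
    seq : str
        RNA (or DNA; T is read as U) sequence.  Ambiguous characters are
        treated as unpairable but present.
    params : EnergyParameters, optional
        Defaults to the bundled Turner 2004 tables.
    W : int
        Maximal span: bases can pair only when the paired region covers at
        most ``W`` bases.  Required; clamped to the sequence length.
    loop_cap : int
        Maximal total unpaired length of a bulge/internal loop.
    """
    norm = normalize(seq) if isinstance(seq, str) else None
    it = fold.inside(norm if norm is not None else seq, params, W, loop_cap)
    for attempt in range(4):
        ot = fold.outside(None, inside_tables=it)
        a, b = it.alpha, ot.beta
        prof = _kernels.profile_kernel(
            it.codes, it.indexing.W, it.indexing.C, it.eta, PAIR_TYPE,
            it._tw, a["Stem"], a["StemEnd"], a["Multi"], a["Multi2"],
            it.alpha_outer_log, b["Stem"], b["StemEnd"], b["Multi"],
            b["Multi2"], ot.beta_outer_log)
        if np.isfinite(prof).all():
            # float rounding can leave entries an ulp outside [0, 1]
            prof[(prof < 0.0) & (prof > -1e-9)] = 0.0
            prof[(prof > 1.0) & (prof < 1.0 + 1e-9)] = 1.0
            break
        # overflow in the banded tables: rerun with stronger rescaling
        it = fold.inside(it.codes, it.params, it.indexing.W, loop_cap,
                         eta=it.eta + 0.7)
    else:
        raise FloatingPointError("profile did not stabilize numerically")
    if norm is None:
        norm = "".join("ACGUN"[c] for c in np.asarray(it.codes))
    return StructuralProfile(name, norm, prof, it.indexing.W)


def unstructured_track(profile: StructuralProfile) -> np.ndarray:
    """Per-position probability of the unstructured context (E + M)."""
    return profile.unstructured
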