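"""Secondary-structure features (18 dimensions).

From a predicted state string S over {H, E, C} of length L and its L x 3
probability matrix (columns C, H, E), six small families are assembled in a
frozen order:

1. state frequencies T(H)/L, T(E)/L, T(C)/L                     (3)
2. positional sums: for each state, the sum of its 1-based position
   indices divided by L(L-1)                                     (3)
3. longest-run lengths MAX(L_H)/L, MAX(L_E)/L, MAX(L_C)/L        (3)
4. transition probabilities between collapsed helix (alpha) and
   sheet (beta) segments: after deleting C and collapsing maximal
   H-runs to alpha and E-runs to beta, the pair counts fill

       TPM = [ T(aa)/(T(aa)+T(ab))  T(ab)/(T(aa)+T(ab)) ]
             [ T(ba)/(T(bb)+T(ba))  T(bb)/(T(bb)+T(ba)) ]

   reported row-major plus the two column averages; a row whose
   denominator is 0 is zero-filled (real predictions can lack H or
   E entirely — zero is the conventional "no signal" encoding)     (6)
5. probability-matrix column means, order C, H, E                (3)
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import LengthError
from .types import FeatureMatrix, StructurePrediction

N_FEATURES = 18


@dataclass(frozen=True)
class TransitionMatrix:
    """2 x 2 alpha/beta segment transition probabilities plus raw pair counts."""

    tpm: np.ndarray
    counts: dict[str, int]


def composition_features(sp: StructurePrediction) -> np.ndarray:
    """State frequencies in order H, E, C; sums to 1."""
    L = len(sp)
    return np.array([sp.states.count(s) / L for s in "HEC"])


def positional_features(sp: StructurePrediction) -> np.ndarray:
    """Per-state sums of 1-based position indices over L(L-1)."""
    L = len(sp)
    if L < 2:
        raise LengthError(
            f"structure {sp.sequence_id!r}: length {L} < 2; positional "
            f"denominator L(L-1) vanishes"
        )
    denom = L * (L - 1)
    out = np.zeros(3)
    for pos, state in enumerate(sp.states, start=1):
        out["HEC".index(state)] += pos
    return out / denom


def _max_run(states: str, state: str) -> int:
    runs = re.findall(f"{state}+", states)
    return max((len(r) for r in runs), default=0)


def maxrun_features(sp: StructurePrediction) -> np.ndarray:
    """Longest contiguous run of each state divided by L, order H, E, C."""
    L = len(sp)
    return np.array([_max_run(sp.states, s) / L for s in "HEC"])


def collapse_segments(states: str) -> str:
    """Delete C, collapse H-runs to 'a' (alpha) and E-runs to 'b' (beta)."""
    no_coil = states.replace("C", "")
    collapsed = re.sub(r"H+", "a", no_coil)
    return re.sub(r"E+", "b", collapsed)


def transition_matrix(sp: StructurePrediction) -> TransitionMatrix:
    """Alpha/beta transition probabilities from the collapsed segment string."""
    s0 = collapse_segments(sp.states)
    counts = {"aa": 0, "ab": 0, "ba": 0, "bb": 0}
    for pair in zip(s0, s0[1:]):
        counts["".join(pair)] += 1
    tpm = np.zeros((2, 2))
    row1 = counts["aa"] + counts["ab"]
    if row1 > 0:
        tpm[0] = [counts["aa"] / row1, counts["ab"] / row1]
    row2 = counts["bb"] + counts["ba"]
    if row2 > 0:
        tpm[1] = [counts["ba"] / row2, counts["bb"] / row2]
    return TransitionMatrix(tpm, counts)


def tpm_features(tm: TransitionMatrix) -> np.ndarray:
    """Row-major TPM entries followed by the two column averages."""
    t = tm.tpm
    return np.array(
        [t[0, 0], t[0, 1], t[1, 0], t[1, 1],
         (t[0, 0] + t[1, 0]) / 2, (t[0, 1] + t[1, 1]) / 2]
    )


def spm_features(sp: StructurePrediction) -> np.ndarray:
    """Column means of the probability matrix, order C, H, E."""
    return sp.probabilities.mean(axis=0)


def sss_features(sp: StructurePrediction) -> np.ndarray:
    """The assembled 18-dimensional secondary-structure vector."""
    return np.concatenate(
        [
            composition_features(sp),
            positional_features(sp),
            maxrun_features(sp),
            tpm_features(transition_matrix(sp)),
            spm_features(sp),
        ]
    )


class SssFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer mapping structure predictions to the 18-feature vector."""

    schema = "sss18"

    def fit(self, X: list[StructurePrediction], y=None) -> "SssFeaturizer":
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X: list[StructurePrediction]) -> np.ndarray:
        return np.array([sss_features(sp) for sp in X])

    def transform_matrix(
        self, X: list[StructurePrediction], labels=None
    ) -> FeatureMatrix:
        return FeatureMatrix(
            ids=[sp.sequence_id for sp in X],
            values=self.fit(X).transform(X),
            schema=self.schema,
            labels=labels,
        )
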