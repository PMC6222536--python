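"""Evolutionary-profile features: 20 column means + 380 cross correlations.

The raw L x 20 log-odds profile is squashed elementwise by the logistic
function A = 1 / (1 + exp(-a)) into (0, 1).  Two feature families follow:

* ``pssm20`` — the 20 column means of A.
* ``pssm380`` — for every ordered residue-column pair (s, t) with s != t
  and lag g = |s - t|, the lagged normalized cross-correlation

      (1 / (L - g)) * sum_{i=1..L-g} (A[i, s] - F_s)(A[i+g, t] - F_t)
                                     / (sd_s * sd_t)

  with F the column means and sd the *population* column standard
  deviations (divisor L).  With the population convention the same
  expression evaluated at s = t (g = 0) is identically 1 for every
  non-degenerate column — the diagonal is uninformative and dropped,
  leaving 380 features in lexicographic (s, t) order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._alphabet import PSSM_ORDER
from .errors import DegenerateInputError, LengthError
from .types import FeatureMatrix, ProfileMatrix

#: minimum length so that L - g >= 1 for every lag g = |s - t| <= 19
MIN_LENGTH_380 = 20


@dataclass(frozen=True)
class NormalizedProfile:
    """Sigmoid-squashed profile with cached column means and population SDs."""

    sequence_id: str
    A: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray

    def __len__(self) -> int:
        return self.A.shape[0]


def sigmoid_normalize(profile: ProfileMatrix) -> NormalizedProfile:
    """Elementwise logistic squashing of the raw log-odds scores."""
    profile = profile.reordered(PSSM_ORDER)
    A = 1.0 / (1.0 + np.exp(-profile.scores))
    return NormalizedProfile(
        sequence_id=profile.sequence_id,
        A=A,
        column_means=A.mean(axis=0),
        column_sds=A.std(axis=0),  # population, divisor L
    )


def pssm20(profile: NormalizedProfile) -> np.ndarray:
    """The 20 sigmoid column means."""
    return profile.column_means.copy()


def pssm380(profile: NormalizedProfile) -> np.ndarray:
    """The 380 lagged cross-column correlations (ordered pairs, s != t)."""
    L = len(profile)
    if L < MIN_LENGTH_380:
        raise LengthError(
            f"profile {profile.sequence_id!r}: length {L} < {MIN_LENGTH_380} "
            f"required for lag-19 cross correlations"
        )
    zero = np.flatnonzero(profile.column_sds == 0)
    if zero.size:
        raise DegenerateInputError(
            f"profile {profile.sequence_id!r}: column(s) "
            f"{[PSSM_ORDER[j] for j in zero]} have zero variance"
        )
    centered = profile.A - profile.column_means
    sds = profile.column_sds
    out = np.empty(380)
    k = 0
    for s in range(20):
        for t in range(20):
            if s == t:
                continue
            g = abs(s - t)
            prod = centered[: L - g, s] * centered[g:, t]
            out[k] = prod.mean() / (sds[s] * sds[t])
            k += 1
    return out


def pssm_features(profile: ProfileMatrix) -> np.ndarray:
    """Concatenated 400-dimensional profile feature vector (20 + 380)."""
    norm = sigmoid_normalize(profile)
    return np.concatenate([pssm20(norm), pssm380(norm)])


class PssmFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer mapping raw profiles to one of the profile schemas.

    Parameters
    ----------
    block : ``"pssm20"``, ``"pssm380"`` or ``"pssm400"`` — which feature
        block to emit.
    """

    def __init__(self, block: str = "pssm400"):
        self.block = block

    @property
    def schema(self) -> str:
        return self.block

    def fit(self, X: list[ProfileMatrix], y=None) -> "PssmFeaturizer":
        if self.block not in ("pssm20", "pssm380", "pssm400"):
            raise ValueError(f"unknown profile feature block {self.block!r}")
        self.n_features_out_ = {"pssm20": 20, "pssm380": 380, "pssm400": 400}[self.block]
        return self

    def transform(self, X: list[ProfileMatrix]) -> np.ndarray:
        self.fit(X)
        rows = []
        for profile in X:
            norm = sigmoid_normalize(profile)
            if self.block == "pssm20":
                rows.append(pssm20(norm))
            elif self.block == "pssm380":
                rows.append(pssm380(norm))
            else:
                rows.append(np.concatenate([pssm20(norm), pssm380(norm)]))
        return np.array(rows)

    def transform_matrix(
        self, X: list[ProfileMatrix], labels=None
    ) -> FeatureMatrix:
        return FeatureMatrix(
            ids=[p.sequence_id for p in X],
            values=self.transform(X),
            schema=self.schema,
            labels=labels,
        )
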