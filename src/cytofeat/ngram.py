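"""Weighted n-gram composition features (N = 2; 420 dimensions).

The feature value of a length-``n`` segment ``g`` is

    (20^n / (20 + 400)) * T(g) / (L - n + 1)

where ``T(g)`` counts the occurrences of ``g`` among the overlapping
length-``n`` windows of the sequence.  The per-order prefactor weights each
normalized count so that the 20 monomer slots sum to 20/420, the 400 dimer
slots sum to 400/420, and the whole vector sums to exactly 1.

Slot order: 20 monomers in alphabetical order, then 400 dimers row-major
(first residue, second residue) in the same order.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._alphabet import ALPHA_ORDER
from .errors import LengthError
from .types import FeatureMatrix, ProteinSequence

#: total slot count: 20 + 20^2
N_FEATURES = 420

_MONO_WEIGHT = 20 / 420
_DI_WEIGHT = 400 / 420
_INDEX = {a: i for i, a in enumerate(ALPHA_ORDER)}


def ngram_features(seq: ProteinSequence) -> np.ndarray:
    """The 420-dimensional weighted monomer + dimer composition vector."""
    L = len(seq)
    if L < 2:
        raise LengthError(
            f"sequence {seq.id!r}: length {L} < 2; the dimer block is undefined"
        )
    out = np.zeros(N_FEATURES)
    for ch in seq.residues:
        out[_INDEX[ch]] += 1.0
    out[:20] *= _MONO_WEIGHT / L
    for a, b in zip(seq.residues, seq.residues[1:]):
        out[20 + 20 * _INDEX[a] + _INDEX[b]] += 1.0
    out[20:] *= _DI_WEIGHT / (L - 1)
    return out


class NGramFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping protein sequences to n-gram vectors.

    ``transform`` accepts a list of :class:`ProteinSequence` and returns an
    (n, 420) array; :meth:`transform_matrix` wraps it in a schema-tagged
    :class:`FeatureMatrix`.
    """

    schema = "ngram420"

    def fit(self, X: list[ProteinSequence], y=None) -> "NGramFeaturizer":
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X: list[ProteinSequence]) -> np.ndarray:
        return np.array([ngram_features(seq) for seq in X])

    def transform_matrix(
        self, X: list[ProteinSequence], labels=None
    ) -> FeatureMatrix:
        return FeatureMatrix(
            ids=[s.id for s in X],
            values=self.fit(X).transform(X),
            schema=self.schema,
            labels=labels,
        )
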