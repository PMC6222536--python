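"""Validated domain containers: sequences, profiles, structure predictions.

The three input kinds the toolkit consumes are a protein sequence, its
evolutionary profile (an L x 20 position-specific scoring matrix from an
iterative profile search) and its predicted secondary structure (a state
string over H/E/C plus an L x 3 per-residue probability matrix).  Each is
validated on construction; downstream feature code can then assume the
invariants hold.

Internally coordinates are 0-based with half-open ranges; error messages
use 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._alphabet import AMINO_ACIDS, PSSM_ORDER, SS_STATES
from .errors import LengthError, ValidationError

#: minimum sequence length for the PSSM-380 and PseAAC feature families
MIN_PROFILE_LENGTH = 20


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20-letter standard amino-acid alphabet.

    Ambiguity codes (B, J, O, U, X, Z) are rejected rather than remapped;
    there is no principled mapping onto the 20 standard residues.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: empty residue string")
        for pos, ch in enumerate(self.residues):
            if ch not in AMINO_ACIDS:
                raise ValidationError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position "
                    f"{pos + 1} (only the 20 standard amino acids are allowed)"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def require_length(self, minimum: int, context: str) -> None:
        if len(self) < minimum:
            raise LengthError(
                f"sequence {self.id!r}: length {len(self)} < {minimum} "
                f"required for {context}"
            )


@dataclass(frozen=True)
class ProfileMatrix:
    """An L x 20 matrix of raw log-odds substitution scores for one sequence.

    ``scores[i, j]`` is the score of position ``i`` of the sequence evolving
    to residue ``column_order[j]``.  The canonical column order is the one
    the upstream profile-search tool emits.
    """

    sequence_id: str
    scores: np.ndarray
    column_order: str = PSSM_ORDER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValidationError(
                f"profile {self.sequence_id!r}: expected an L x 20 score "
                f"matrix, got shape {scores.shape}"
            )
        if scores.shape[0] == 0:
            raise ValidationError(f"profile {self.sequence_id!r}: zero rows")
        if sorted(self.column_order) != sorted(PSSM_ORDER) or len(self.column_order) != 20:
            raise ValidationError(
                f"profile {self.sequence_id!r}: column_order must be a "
                f"permutation of the 20 standard residues"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]

    def reordered(self, column_order: str = PSSM_ORDER) -> "ProfileMatrix":
        """Return a copy with columns permuted into ``column_order``."""
        if column_order == self.column_order:
            return self
        perm = [self.column_order.index(ch) for ch in column_order]
        return ProfileMatrix(self.sequence_id, self.scores[:, perm], column_order)


@dataclass(frozen=True)
class StructurePrediction:
    """Predicted secondary structure: H/E/C state string + L x 3 probabilities.

    The probability columns are ordered (C, H, E), matching the layout of a
    .ss2 prediction file.  Rows of parsed files may deviate from summing to
    exactly one by printing precision; the parser records a warning rather
    than rejecting such rows.
    """

    sequence_id: str
    states: str
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        if not self.states:
            raise ValidationError(f"structure {self.sequence_id!r}: empty state string")
        bad = set(self.states) - set(SS_STATES)
        if bad:
            raise ValidationError(
                f"structure {self.sequence_id!r}: invalid state(s) {sorted(bad)}"
            )
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ValidationError(
                f"structure {self.sequence_id!r}: expected an L x 3 probability "
                f"matrix, got shape {probs.shape}"
            )
        if probs.shape[0] != len(self.states):
            raise ValidationError(
                f"structure {self.sequence_id!r}: {len(self.states)} states but "
                f"{probs.shape[0]} probability rows"
            )

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class FeatureMatrix:
    """A labeled n x d feature block under a registered, frozen schema.

    ``labels`` when present are +1 (cytokine) / -1 (non-cytokine).
    """

    ids: list[str]
    values: np.ndarray
    schema: str
    labels: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        from .schemas import feature_names as registry_names

        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.ids), -1)
        expected = registry_names(self.schema)
        if not self.feature_names:
            self.feature_names = list(expected)
        if self.feature_names != list(expected):
            from .errors import SchemaError

            raise SchemaError(
                f"feature names do not match registered schema {self.schema!r}"
            )
        if self.values.shape != (len(self.ids), len(expected)):
            from .errors import SchemaError

            raise SchemaError(
                f"schema {self.schema!r} expects shape "
                f"({len(self.ids)}, {len(expected)}), got {self.values.shape}"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence ids in feature matrix")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.ids),):
                raise ValidationError("labels length does not match ids")
            if not set(np.unique(self.labels)) <= {-1, 1}:
                raise ValidationError("labels must be +1 or -1")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: np.ndarray) -> "FeatureMatrix":
        """Row subset preserving schema and label alignment."""
        idx = np.asarray(indices)
        return FeatureMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[idx],
            schema=self.schema,
            labels=None if self.labels is None else self.labels[idx],
        )
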