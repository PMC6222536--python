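"""Type-I pseudo amino-acid composition (20 + lambda dimensions).

The first 20 slots are the relative residue frequencies f(a_i); the last
``lam`` slots are sequence-order correlation factors built from three
z-score-normalized physicochemical properties — hydrophilicity H1,
hydrophobicity H2 and side-chain mass M.  The tier-g correlation factor is

    b_g = (1 / (L - g)) * sum_{i=1..L-g} (1/3) [ (H1_i - H1_{i+g})^2
                                               + (H2_i - H2_{i+g})^2
                                               + (M_i  - M_{i+g})^2 ]

and the final vector shares one denominator

    D = sum_i f(a_i) + w * sum_g b_g ,

so all 20 + lam slots are non-negative and sum to 1.  Defaults lam = 10,
w = 0.05 give the standard 30-dimensional vector.

The composition terms use raw relative frequencies: z-scoring them could
drive the shared denominator to zero or below, breaking the probability-like
contract of the vector.  Z-scoring applies to the property columns only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._alphabet import ALPHA_ORDER
from .errors import DegenerateInputError, LengthError
from .io import read_property_table
from .types import FeatureMatrix, ProteinSequence

DEFAULT_LAMBDA = 10
DEFAULT_WEIGHT = 0.05


@dataclass(frozen=True)
class PropertyTable:
    """Per-residue H1/H2/M values, raw or z-score normalized.

    Columns are aligned with the alphabetical residue order.
    """

    h1: np.ndarray
    h2: np.ndarray
    mass: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        for name in ("h1", "h2", "mass"):
            col = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, col)
            if col.shape != (20,) or not np.all(np.isfinite(col)):
                raise DegenerateInputError(
                    f"property column {name!r} must hold 20 finite values"
                )

    def columns(self) -> np.ndarray:
        return np.stack([self.h1, self.h2, self.mass], axis=1)


def load_property_table(path: str | Path | None = None) -> PropertyTable:
    """Load the shipped (or a user-supplied) physicochemical constant table."""
    if path is None:
        source = resources.files("cytofeat.data").joinpath("properties.tsv")
        with resources.as_file(source) as p:
            raw = read_property_table(p)
    else:
        raw = read_property_table(path)
    h1 = [raw[a][0] for a in ALPHA_ORDER]
    h2 = [raw[a][1] for a in ALPHA_ORDER]
    mass = [raw[a][2] for a in ALPHA_ORDER]
    return PropertyTable(np.array(h1), np.array(h2), np.array(mass))


def normalize_properties(raw: PropertyTable) -> PropertyTable:
    """Z-score each property column over the 20 residues (population SD)."""
    if raw.normalized:
        return raw
    cols = {}
    for name in ("h1", "h2", "mass"):
        col = getattr(raw, name)
        sd = col.std()  # population SD, divisor 20
        if sd == 0:
            raise DegenerateInputError(
                f"property column {name!r} is constant; z-score undefined"
            )
        cols[name] = (col - col.mean()) / sd
    return PropertyTable(cols["h1"], cols["h2"], cols["mass"], normalized=True)


def correlation_factors(
    seq: ProteinSequence, table: PropertyTable, lam: int = DEFAULT_LAMBDA
) -> np.ndarray:
    """Tier correlation factors b_1 .. b_lam (averaged squared property gaps)."""
    if lam < 1:
        raise ValueError(f"lam must be >= 1, got {lam}")
    L = len(seq)
    if L <= lam:
        raise LengthError(
            f"sequence {seq.id!r}: length {L} must exceed lambda={lam}"
        )
    norm = normalize_properties(table)
    idx = np.array([ALPHA_ORDER.index(ch) for ch in seq.residues])
    props = norm.columns()[idx]  # L x 3
    out = np.empty(lam)
    for g in range(1, lam + 1):
        diff = props[:-g] - props[g:]
        out[g - 1] = np.mean(np.sum(diff**2, axis=1) / 3.0)
    return out


def pseaac_features(
    seq: ProteinSequence,
    table: PropertyTable | None = None,
    lam: int = DEFAULT_LAMBDA,
    w: float = DEFAULT_WEIGHT,
) -> np.ndarray:
    """The (20 + lam)-dimensional pseudo amino-acid composition vector."""
    if w <= 0:
        raise ValueError(f"weight w must be positive, got {w}")
    if table is None:
        table = load_property_table()
    b = correlation_factors(seq, table, lam)
    freqs = np.zeros(20)
    for ch in seq.residues:
        freqs[ALPHA_ORDER.index(ch)] += 1.0
    freqs /= len(seq)
    denom = freqs.sum() + w * b.sum()
    return np.concatenate([freqs, w * b]) / denom


class PseAACFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer computing pseudo amino-acid composition vectors.

    Parameters
    ----------
    lam : number of sequence-order correlation tiers (default 10).
    w : weight of the correlation block in the shared denominator
        (default 0.05).
    property_table : optional override of the shipped constants.
    """

    schema = "pseaac30"

    def __init__(
        self,
        lam: int = DEFAULT_LAMBDA,
        w: float = DEFAULT_WEIGHT,
        property_table: PropertyTable | None = None,
    ):
        self.lam = lam
        self.w = w
        self.property_table = property_table

    def fit(self, X: list[ProteinSequence], y=None) -> "PseAACFeaturizer":
        self.table_ = (
            load_property_table() if self.property_table is None else self.property_table
        )
        self.n_features_out_ = 20 + self.lam
        return self

    def transform(self, X: list[ProteinSequence]) -> np.ndarray:
        table = getattr(self, "table_", None) or load_property_table()
        return np.array(
            [pseaac_features(seq, table, self.lam, self.w) for seq in X]
        )

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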