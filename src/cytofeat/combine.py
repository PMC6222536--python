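"""Feature-combination recipes with frozen schemas and dimension checks.

Recipes (part order is frozen; the classifier is order-insensitive but the
persisted schema must be deterministic):

* ``sp``   = sss18  + pseaac30          -> 48-D
* ``pssm`` = pssm20 + pssm380           -> 400-D
* ``psp``  = pssm400 + sp48             -> 448-D
* ``pspn`` = ngram420 + psp448          -> 868-D

No feature scaling happens at combine time; scaling is the classifier's
concern.
"""

from __future__ import annotations

import numpy as np

from .errors import AlignmentError, SchemaError
from .types import FeatureMatrix

#: recipe name -> (ordered part schemas, output schema)
RECIPES: dict[str, tuple[tuple[str, ...], str]] = {
    "sp": (("sss18", "pseaac30"), "sp48"),
    "pssm": (("pssm20", "pssm380"), "pssm400"),
    "psp": (("pssm400", "sp48"), "psp448"),
    "pspn": (("ngram420", "psp448"), "pspn868"),
}

#: declared output dimensions, asserted at combine time
RECIPE_DIMENSIONS = {"sp": 48, "pssm": 400, "psp": 448, "pspn": 868}


def combine(parts: list[FeatureMatrix], recipe: str) -> FeatureMatrix:
    """Horizontally concatenate feature blocks according to a named recipe."""
    if recipe not in RECIPES:
        raise SchemaError(f"unknown recipe {recipe!r}; choose from {sorted(RECIPES)}")
    expected_parts, out_schema = RECIPES[recipe]
    got = tuple(p.schema for p in parts)
    if got != expected_parts:
        raise SchemaError(
            f"recipe {recipe!r} needs parts {expected_parts} in order, got {got}"
        )
    first = parts[0]
    for part in parts[1:]:
        if part.ids != first.ids:
            raise AlignmentError(
                f"parts of recipe {recipe!r} do not share the same id order"
            )
    labels = first.labels
    for part in parts[1:]:
        if (labels is None) != (part.labels is None):
            raise AlignmentError("parts disagree on the presence of labels")
        if labels is not None and not np.array_equal(labels, part.labels):
            raise AlignmentError("parts carry conflicting labels")
    values = np.hstack([p.values for p in parts])
    out = FeatureMatrix(ids=list(first.ids), values=values, schema=out_schema,
                        labels=None if labels is None else labels.copy())
    assert out.n_features == RECIPE_DIMENSIONS[recipe]
    return out
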