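"""Frozen feature-schema registry.

Every feature family and combination has a registered schema: a name and an
ordered list of feature names with a fixed dimension.  Combination recipes
concatenate family schemas in a frozen order:

========  ======================================  ====
name      parts                                   dim
========  ======================================  ====
ngram420  20 monomers + 400 dimers                 420
pseaac30  20 composition + 10 order-correlation     30
pssm20    sigmoid column means                      20
pssm380   ordered residue pairs (s, t), s != t     380
pssm400   pssm20 + pssm380                         400
sss18     secondary-structure features              18
sp48      sss18 + pseaac30                          48
psp448    pssm400 + sp48                           448
pspn868   ngram420 + psp448                        868
========  ======================================  ====
"""

from __future__ import annotations

from ._alphabet import ALPHA_ORDER, PSSM_ORDER
from .errors import SchemaError


def _ngram_names() -> list[str]:
    mono = [f"g1_{a}" for a in ALPHA_ORDER]
    di = [f"g2_{a}{b}" for a in ALPHA_ORDER for b in ALPHA_ORDER]
    return mono + di


def _pseaac_names(lam: int = 10) -> list[str]:
    return [f"comp_{a}" for a in ALPHA_ORDER] + [f"corr_{g}" for g in range(1, lam + 1)]


def _pssm20_names() -> list[str]:
    return [f"colmean_{a}" for a in PSSM_ORDER]


def _pssm380_names() -> list[str]:
    # lexicographic ordered pairs (s, t), s != t, over the profile column order
    return [
        f"cross_{PSSM_ORDER[s]}{PSSM_ORDER[t]}"
        for s in range(20)
        for t in range(20)
        if s != t
    ]


def _sss_names() -> list[str]:
    return [
        "freq_H", "freq_E", "freq_C",
        "pos_H", "pos_E", "pos_C",
        "maxrun_H", "maxrun_E", "maxrun_C",
        "tpm_aa", "tpm_ab", "tpm_ba", "tpm_bb", "tpm_col1_mean", "tpm_col2_mean",
        "spm_C", "spm_H", "spm_E",
    ]


_REGISTRY: dict[str, list[str]] = {}


def _register(name: str, names: list[str]) -> None:
    _REGISTRY[name] = names


_register("ngram420", _ngram_names())
_register("pseaac30", _pseaac_names())
_register("pssm20", _pssm20_names())
_register("pssm380", _pssm380_names())
_register("pssm400", _pssm20_names() + _pssm380_names())
_register("sss18", _sss_names())
_register("sp48", _sss_names() + _pseaac_names())
_register("psp448", _REGISTRY["pssm400"] + _REGISTRY["sp48"])
_register("pspn868", _REGISTRY["ngram420"] + _REGISTRY["psp448"])


def feature_names(schema: str) -> list[str]:
    """The ordered feature names of a registered schema."""
    try:
        return list(_REGISTRY[schema])
    except KeyError:
        raise SchemaError(
            f"unknown feature schema {schema!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def dimension(schema: str) -> int:
    return len(feature_names(schema))


def registered_schemas() -> list[str]:
    return sorted(_REGISTRY)
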