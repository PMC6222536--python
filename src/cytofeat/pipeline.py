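"""End-to-end extraction: from input views to a combined feature matrix.

Glues the per-family featurizers and the combination recipes together, for
both in-memory objects and on-disk dataset directories (FASTA + per-id
``pssm/<id>.pssm`` and ``ss2/<id>.ss2`` files).  Sequences whose auxiliary
files are missing are skipped with a logged warning and counted, mirroring
how incomplete records are dropped during dataset preparation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .combine import RECIPES, combine
from .errors import ValidationError
from .io import parse_pssm, parse_ss2, read_fasta
from .ngram import NGramFeaturizer
from .pseaac import PseAACFeaturizer
from .pssm import PssmFeaturizer
from .sss import SssFeaturizer
from .types import (
    FeatureMatrix,
    ProfileMatrix,
    ProteinSequence,
    StructurePrediction,
)

logger = logging.getLogger(__name__)

#: which input views each extractable schema needs
SCHEMA_INPUTS = {
    "ngram420": ("seq",),
    "pseaac30": ("seq",),
    "pssm20": ("profile",),
    "pssm380": ("profile",),
    "pssm400": ("profile",),
    "sss18": ("structure",),
    "sp48": ("seq", "structure"),
    "psp448": ("seq", "profile", "structure"),
    "pspn868": ("seq", "profile", "structure"),
}


def extract_features(
    schema: str,
    sequences: list[ProteinSequence] | None = None,
    profiles: list[ProfileMatrix] | None = None,
    structures: list[StructurePrediction] | None = None,
    labels: np.ndarray | None = None,
) -> FeatureMatrix:
    """Extract any registered schema (family or combination) in one call."""
    if schema not in SCHEMA_INPUTS:
        raise ValidationError(f"schema {schema!r} is not extractable")

    def need(view, name):
        if view is None:
            raise ValidationError(f"schema {schema!r} requires {name} input")
        return view

    if schema == "ngram420":
        return NGramFeaturizer().transform_matrix(need(sequences, "sequence"), labels)
    if schema == "pseaac30":
        return PseAACFeaturizer().transform_matrix(need(sequences, "sequence"), labels)
    if schema in ("pssm20", "pssm380", "pssm400"):
        return PssmFeaturizer(block=schema).transform_matrix(
            need(profiles, "profile"), labels
        )
    if schema == "sss18":
        return SssFeaturizer().transform_matrix(need(structures, "structure"), labels)
    if schema == "sp48":
        return combine(
            [
                extract_features("sss18", structures=need(structures, "structure"), labels=labels),
                extract_features("pseaac30", sequences=need(sequences, "sequence"), labels=labels),
            ],
            "sp",
        )
    if schema == "psp448":
        return combine(
            [
                extract_features("pssm400", profiles=need(profiles, "profile"), labels=labels),
                extract_features(
                    "sp48", sequences=sequences, structures=structures, labels=labels
                ),
            ],
            "psp",
        )
    # pspn868
    return combine(
        [
            extract_features("ngram420", sequences=need(sequences, "sequence"), labels=labels),
            extract_features(
                "psp448",
                sequences=sequences,
                profiles=profiles,
                structures=structures,
                labels=labels,
            ),
        ],
        "pspn",
    )


RECIPE_SCHEMAS = {name: RECIPES[name][1] for name in RECIPES}


def load_dataset_dir(
    fasta: str | Path,
    pssm_dir: str | Path | None = None,
    ss2_dir: str | Path | None = None,
    labels_path: str | Path | None = None,
) -> tuple[
    list[ProteinSequence],
    list[ProfileMatrix] | None,
    list[StructurePrediction] | None,
    np.ndarray | None,
]:
    """Load sequences plus whichever auxiliary views are available.

    A sequence missing a required ``<id>.pssm`` / ``<id>.ss2`` file is
    dropped with a warning; the summary count is logged.
    """
    sequences = read_fasta(fasta)
    label_map: dict[str, int] | None = None
    if labels_path is not None:
        label_map = {}
        for line in Path(labels_path).read_text().splitlines()[1:]:
            if line.strip():
                seq_id, label = line.split("\t")
                label_map[seq_id] = int(label)

    kept: list[ProteinSequence] = []
    profiles: list[ProfileMatrix] = []
    structures: list[StructurePrediction] = []
    skipped = 0
    for seq in sequences:
        profile = structure = None
        if pssm_dir is not None:
            path = Path(pssm_dir) / f"{seq.id}.pssm"
            if not path.exists():
                logger.warning("skipping %s: missing %s", seq.id, path)
                skipped += 1
                continue
            profile = parse_pssm(path, seq.id)
            if len(profile) != len(seq):
                raise ValidationError(
                    f"profile for {seq.id!r} has {len(profile)} rows but the "
                    f"sequence has {len(seq)} residues"
                )
        if ss2_dir is not None:
            path = Path(ss2_dir) / f"{seq.id}.ss2"
            if not path.exists():
                logger.warning("skipping %s: missing %s", seq.id, path)
                skipped += 1
                continue
            structure = parse_ss2(path, seq.id)
            if len(structure) != len(seq):
                raise ValidationError(
                    f"structure for {seq.id!r} has {len(structure)} rows but "
                    f"the sequence has {len(seq)} residues"
                )
        kept.append(seq)
        if profile is not None:
            profiles.append(profile)
        if structure is not None:
            structures.append(structure)
    if skipped:
        logger.warning("skipped %d sequence(s) with missing auxiliary files", skipped)

    labels = None
    if label_map is not None:
        missing = [s.id for s in kept if s.id not in label_map]
        if missing:
            raise ValidationError(f"no label for sequence(s) {missing[:5]}")
        labels = np.array([label_map[s.id] for s in kept])
    return (
        kept,
        profiles if pssm_dir is not None else None,
        structures if ss2_dir is not None else None,
        labels,
    )
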