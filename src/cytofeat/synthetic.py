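"""Synthetic (sequence, profile, structure, label) fixture generation.

Emulates the data regime the toolkit is built for — two classes of protein
sequences of length >= 20, each paired with an evolutionary profile and a
secondary-structure prediction — with controllable class separation, so
every pipeline stage is testable without external databases or prediction
software.

Generative model (signals are drawn independently given the class; the
simplest scheme in which every feature family is individually
informative):

* residues — class-conditional multinomials.  Negatives are uniform over
  the 20 residues; positives are uniform tilted by ``effect_size`` toward
  a fixed five-residue subset (weight ``1 + effect_size`` inside the
  subset, 1 outside).  ``effect_size = 0`` collapses both classes onto the
  same distribution.
* profiles — position i scores ``+conservation`` on the true residue
  column and ``-1`` elsewhere, plus integer-rounded Gaussian noise of SD
  ``pssm_noise``; written in the ASCII profile dialect the parser accepts.
* structure — a hidden 3-state Markov chain over {H, E, C} with stay
  probability 0.8 and class-shifted state propensities (positives tilted
  toward helix, away from sheet, by ``structure_bias``); per-row
  probability triples put 0.8 on the realized state and 0.1 elsewhere.

Everything is driven by one integer seed; identical configurations give
byte-identical output directories.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._alphabet import ALPHA_ORDER, PSSM_ORDER, SS_STATES
from .errors import ValidationError
from .io import write_fasta, write_pssm, write_ss2
from .types import ProfileMatrix, ProteinSequence, StructurePrediction

#: residues whose frequency is tilted upward in the positive class
POSITIVE_RESIDUE_SUBSET = "LIVFM"

_STAY_PROBABILITY = 0.8
_TRUE_STATE_PROBABILITY = 0.8


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_pos: int = 100
    n_neg: int = 100
    min_length: int = 30
    max_length: int = 60
    effect_size: float = 1.0
    structure_bias: float = 0.5
    pssm_noise: float = 1.0
    conservation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 20:
            raise ValidationError(
                "min_length must be >= 20 (profile-correlation and PseAAC "
                "features need length >= 20)"
            )
        if self.max_length < self.min_length:
            raise ValidationError("max_length must be >= min_length")
        if self.effect_size < 0 or self.pssm_noise < 0:
            raise ValidationError("effect_size and pssm_noise must be >= 0")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValidationError("class sizes must be non-negative")


def _residue_weights(label: int, effect_size: float) -> np.ndarray:
    # exponential tilt: calibrated so that effect_size >= 1 makes the two
    # classes clearly separable on composition features alone
    w = np.ones(20)
    if label == 1:
        for ch in POSITIVE_RESIDUE_SUBSET:
            w[ALPHA_ORDER.index(ch)] = np.exp(effect_size)
    return w / w.sum()


def gen_sequences(cfg: GeneratorConfig) -> list[tuple[ProteinSequence, int]]:
    """Draw labeled sequences from the class-conditional residue model."""
    rng = np.random.default_rng(cfg.seed)
    out: list[tuple[ProteinSequence, int]] = []
    labels = [1] * cfg.n_pos + [-1] * cfg.n_neg
    width = len(str(max(len(labels), 1)))
    for i, label in enumerate(labels):
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        probs = _residue_weights(label, cfg.effect_size)
        residues = "".join(
            ALPHA_ORDER[j] for j in rng.choice(20, size=length, p=probs)
        )
        tag = "pos" if label == 1 else "neg"
        out.append((ProteinSequence(id=f"{tag}{i:0{width}d}", residues=residues), label))
    return out


def gen_profile(
    seq: ProteinSequence,
    pssm_noise: float = 1.0,
    conservation: float = 5.0,
    seed: int = 0,
) -> ProfileMatrix:
    """Conservation-plus-noise profile for one sequence (integer scores)."""
    rng = np.random.default_rng(seed)
    scores = -np.ones((len(seq), 20))
    for i, ch in enumerate(seq.residues):
        scores[i, PSSM_ORDER.index(ch)] = conservation
    if pssm_noise > 0:
        scores += np.rint(rng.normal(0.0, pssm_noise, size=scores.shape))
    return ProfileMatrix(seq.id, scores)


def gen_pssm(
    seq: ProteinSequence,
    path: str | Path,
    pssm_noise: float = 1.0,
    conservation: float = 5.0,
    seed: int = 0,
) -> ProfileMatrix:
    """Generate a profile and write it as an ASCII profile file."""
    profile = gen_profile(seq, pssm_noise, conservation, seed)
    write_pssm(seq, profile.scores, path)
    return profile


def _state_weights(label: int, structure_bias: float) -> np.ndarray:
    # order H, E, C; positives tilted toward helix and away from sheet
    if label == 1:
        w = np.array([np.exp(structure_bias), np.exp(-structure_bias), 1.0])
    else:
        w = np.ones(3)
    return w / w.sum()


def gen_structure(
    seq: ProteinSequence,
    structure_bias: float = 0.5,
    label: int = -1,
    seed: int = 0,
) -> StructurePrediction:
    """Markov-chain structure prediction for one sequence."""
    rng = np.random.default_rng(seed)
    weights = _state_weights(label, structure_bias)
    states: list[str] = [SS_STATES[rng.choice(3, p=weights)]]
    for _ in range(len(seq) - 1):
        if rng.random() < _STAY_PROBABILITY:
            states.append(states[-1])
        else:
            states.append(SS_STATES[rng.choice(3, p=weights)])
    probs = np.full((len(seq), 3), (1 - _TRUE_STATE_PROBABILITY) / 2)
    for i, state in enumerate(states):
        probs[i, "CHE".index(state)] = _TRUE_STATE_PROBABILITY
    return StructurePrediction(seq.id, "".join(states), probs)


def gen_ss2(
    seq: ProteinSequence,
    path: str | Path,
    structure_bias: float = 0.5,
    label: int = -1,
    seed: int = 0,
) -> StructurePrediction:
    """Generate a structure prediction and write it as a .ss2 file."""
    sp = gen_structure(seq, structure_bias, label, seed)
    write_ss2(seq, sp, path)
    return sp


@dataclass
class SyntheticDataset:
    """In-memory triple-view dataset plus labels."""

    sequences: list[ProteinSequence]
    profiles: list[ProfileMatrix]
    structures: list[StructurePrediction]
    labels: np.ndarray
    config: GeneratorConfig


def gen_objects(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate the full dataset as in-memory domain objects."""
    pairs = gen_sequences(cfg)
    # one spawned child seed per sequence and view keeps files reproducible
    seed_rng = np.random.default_rng(cfg.seed + 1)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=(len(pairs), 2))
    profiles = []
    structures = []
    for (seq, label), (s_pssm, s_ss2) in zip(pairs, child_seeds):
        profiles.append(
            gen_profile(seq, cfg.pssm_noise, cfg.conservation, int(s_pssm))
        )
        structures.append(
            gen_structure(seq, cfg.structure_bias, label, int(s_ss2))
        )
    return SyntheticDataset(
        sequences=[seq for seq, _ in pairs],
        profiles=profiles,
        structures=structures,
        labels=np.array([label for _, label in pairs]),
        config=cfg,
    )


def gen_dataset(cfg: GeneratorConfig, out_dir: str | Path) -> SyntheticDataset:
    """Write a self-consistent fixture directory: FASTA + profiles + ss2.

    Layout: ``sequences.fasta``, ``labels.tsv`` (id, label), ``pssm/<id>.pssm``,
    ``ss2/<id>.ss2`` and a ``manifest.json`` recording the configuration.
    """
    out = Path(out_dir)
    (out / "pssm").mkdir(parents=True, exist_ok=True)
    (out / "ss2").mkdir(parents=True, exist_ok=True)
    data = gen_objects(cfg)
    write_fasta(data.sequences, out / "sequences.fasta")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("id\tlabel\n")
        for seq, label in zip(data.sequences, data.labels):
            fh.write(f"{seq.id}\t{int(label)}\n")
    for seq, profile, structure in zip(data.sequences, data.profiles, data.structures):
        write_pssm(seq, profile.scores, out / "pssm" / f"{seq.id}.pssm")
        write_ss2(seq, structure, out / "ss2" / f"{seq.id}.ss2")
    manifest = {"config": asdict(cfg), "n_sequences": len(data.sequences)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return data
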