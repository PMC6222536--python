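"""Readers and writers for every external format the toolkit touches.

Formats
-------
* multi-record FASTA (via Biopython)
* PSI-BLAST ASCII profile files (the ``-out_ascii_pssm`` dialect): a header
  naming the 20 score columns, then one row per position carrying the
  position index, the residue, 20 log-odds integers, and optionally 20
  weighted-percentage columns plus trailing statistics.  Only the first 20
  (log-odds) columns are retained.
* PSI-PRED ``.ss2`` predictions: a comment header, then one row per residue
  with index, residue, state letter and three probabilities in (C, H, E)
  order.
* tab-separated feature tables with a schema line, one header row of
  feature names, and one ``id`` + ``label`` column pair per data row.
  Numeric payloads round-trip bit-exactly (``repr`` serialization).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._alphabet import PSSM_ORDER, SS_STATES
from .errors import ParseError, SchemaError, ValidationError
from .schemas import feature_names
from .types import FeatureMatrix, ProfileMatrix, ProteinSequence, StructurePrediction

_NA_LABEL = "NA"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record FASTA file into validated sequences.

    Ids are the header words up to the first whitespace; residues are
    upper-cased.  A residue outside the 20-letter standard alphabet raises
    a :class:`ValidationError` naming the sequence and the character — no
    silent substitution.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records and path.stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records found")
    return [ProteinSequence(id=rec.id, residues=str(rec.seq).upper()) for rec in records]


def write_fasta(seqs: list[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def parse_pssm(path: str | Path, sequence_id: str | None = None) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII profile file into a :class:`ProfileMatrix`.

    Keeps only the first 20 (log-odds) score columns; the column order is
    taken from the file's own header line.
    """
    path = Path(path)
    if sequence_id is None:
        sequence_id = path.stem
    lines = path.read_text().splitlines()

    header_idx = None
    column_order = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(len(t) == 1 and t.isalpha() for t in toks[:20]):
            column_order = "".join(toks[:20])
            header_idx = i
            break
    if header_idx is None or column_order is None:
        raise ParseError(f"{path}: no residue-column header line found")
    if sorted(column_order) != sorted(PSSM_ORDER):
        raise ParseError(
            f"{path}: line {header_idx + 1}: header columns are not the 20 "
            f"standard residues"
        )

    rows: list[list[float]] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        toks = line.split()
        if not toks:
            break  # blank line terminates the matrix block
        if not toks[0].isdigit():
            break  # trailing statistics block
        if int(toks[0]) != expected_pos:
            raise ParseError(
                f"{path}: line {lineno}: expected position {expected_pos}, "
                f"got {toks[0]!r}"
            )
        if len(toks) < 22:
            raise ParseError(
                f"{path}: line {lineno}: truncated row ({len(toks) - 2} score "
                f"columns, need 20)"
            )
        try:
            scores = [float(t) for t in toks[2:22]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric score cell ({exc})")
        rows.append(scores)
        expected_pos += 1

    if not rows:
        raise ParseError(f"{path}: profile matrix has no rows")
    return ProfileMatrix(sequence_id, np.array(rows), column_order)


def write_pssm(
    seq: ProteinSequence, scores: np.ndarray, path: str | Path
) -> None:
    """Write an L x 20 integer score matrix in the PSI-BLAST ASCII dialect.

    Emits the log-odds block, a weighted-percentage block of zeros, the two
    per-row statistics columns, and a trailing K/Lambda block — the layout
    :func:`parse_pssm` accepts.
    """
    scores = np.asarray(scores)
    if scores.shape != (len(seq), 20):
        raise ValidationError(
            f"profile for {seq.id!r} must be {len(seq)} x 20, got {scores.shape}"
        )
    header = "  ".join(PSSM_ORDER)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write("            " + header + "   " + header + "\n")
        for i, (residue, row) in enumerate(zip(seq.residues, scores), start=1):
            cells = "".join(f"{int(round(v)):4d}" for v in row)
            pct = "".join(f"{0:4d}" for _ in range(20))
            fh.write(f"{i:5d} {residue} {cells} {pct}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3113\n")


# ---------------------------------------------------------------------------
# PSI-PRED .ss2
# ---------------------------------------------------------------------------

def parse_ss2(path: str | Path, sequence_id: str | None = None) -> StructurePrediction:
    """Parse a PSI-PRED ``.ss2`` prediction file.

    Rows whose probability triple sums outside [0.99, 1.01] are kept with a
    recorded warning; printing precision legitimately produces such rows.
    """
    path = Path(path)
    if sequence_id is None:
        sequence_id = path.stem
    states: list[str] = []
    probs: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        toks = stripped.split()
        if len(toks) < 6:
            raise ParseError(f"{path}: line {lineno}: expected 6 fields, got {len(toks)}")
        state = toks[2]
        if state not in SS_STATES:
            raise ParseError(
                f"{path}: line {lineno}: state {state!r} not in {{C,H,E}}"
            )
        try:
            triple = [float(toks[3]), float(toks[4]), float(toks[5])]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric probability ({exc})")
        if not 0.99 <= sum(triple) <= 1.01:
            warnings.warn(
                f"{path}: line {lineno}: probability row sums to "
                f"{sum(triple):.4f}, keeping row",
                stacklevel=2,
            )
        states.append(state)
        probs.append(triple)
    if not states:
        raise ParseError(f"{path}: no prediction rows")
    return StructurePrediction(sequence_id, "".join(states), np.array(probs))


def write_ss2(
    seq: ProteinSequence, sp: StructurePrediction, path: str | Path
) -> None:
    """Write a structure prediction in the ``.ss2`` dialect."""
    if len(sp) != len(seq):
        raise ValidationError(
            f"structure length {len(sp)} != sequence length {len(seq)} for {seq.id!r}"
        )
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for i, (residue, state, row) in enumerate(
            zip(seq.residues, sp.states, sp.probabilities), start=1
        ):
            fh.write(
                f"{i:4d} {residue} {state}  {row[0]:6.3f} {row[1]:6.3f} {row[2]:6.3f}\n"
            )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Serialize a feature matrix as a schema-tagged TSV (bit-exact floats)."""
    with open(path, "w") as fh:
        fh.write(f"# schema={matrix.schema}\n")
        fh.write("id\tlabel\t" + "\t".join(matrix.feature_names) + "\n")
        labels = matrix.labels
        for i, seq_id in enumerate(matrix.ids):
            label = _NA_LABEL if labels is None else str(int(labels[i]))
            cells = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{seq_id}\t{label}\t{cells}\n" if cells else f"{seq_id}\t{label}\n")


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read a feature table, validating its header against the registry."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# schema="):
        raise ParseError(f"{path}: missing '# schema=' line")
    schema = lines[0].split("=", 1)[1].strip()
    expected = feature_names(schema)
    if len(lines) < 2:
        raise ParseError(f"{path}: missing header row")
    header = lines[1].split("\t")
    if header[:2] != ["id", "label"] or header[2:] != expected:
        raise SchemaError(
            f"{path}: header does not match registered schema {schema!r}"
        )
    ids: list[str] = []
    labels: list[int | None] = []
    values: list[list[float]] = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        toks = line.split("\t")
        if len(toks) != 2 + len(expected):
            raise ParseError(
                f"{path}: line {lineno}: expected {2 + len(expected)} fields, "
                f"got {len(toks)}"
            )
        ids.append(toks[0])
        labels.append(None if toks[1] == _NA_LABEL else int(toks[1]))
        values.append([float(t) for t in toks[2:]])
    has_labels = any(lab is not None for lab in labels)
    if has_labels and any(lab is None for lab in labels):
        raise ParseError(f"{path}: mixed labeled and unlabeled rows")
    arr = np.array(values, dtype=float) if values else np.empty((0, len(expected)))
    return FeatureMatrix(
        ids=ids,
        values=arr,
        schema=schema,
        labels=np.array(labels, dtype=int) if has_labels else None,
    )


# ---------------------------------------------------------------------------
# property tables (PseAAC physicochemical constants)
# ---------------------------------------------------------------------------

def read_property_table(path: str | Path) -> dict[str, tuple[float, float, float]]:
    """Read a 20-row TSV of (residue, hydrophilicity, hydrophobicity, mass)."""
    path = Path(path)
    table: dict[str, tuple[float, float, float]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        toks = stripped.split("\t")
        if len(toks) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 fields, got {len(toks)}")
        residue = toks[0]
        try:
            table[residue] = (float(toks[1]), float(toks[2]), float(toks[3]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value ({exc})")
    if sorted(table) != sorted(PSSM_ORDER):
        raise ParseError(f"{path}: property table must cover exactly the 20 residues")
    return table
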