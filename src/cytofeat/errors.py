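"""Exception hierarchy for cytofeat.

All domain failures derive from :class:`CytofeatError` so callers (and the
CLI) can distinguish validation problems (exit code 1) from usage problems
(exit code 2, handled by click).
"""


class CytofeatError(Exception):
    """Base class for all cytofeat domain errors."""


class ParseError(CytofeatError):
    """A file could not be parsed; the message names the line."""


class ValidationError(CytofeatError):
    """Input violated a domain invariant (alphabet, shape, pairing)."""


class LengthError(ValidationError):
    """A sequence is too short for the requested feature family."""


class SchemaError(ValidationError):
    """A feature matrix does not match its registered schema."""


class AlignmentError(ValidationError):
    """Feature matrices to be combined do not share the same id order."""


class DegenerateInputError(ValidationError):
    """A computation is undefined for this input (zero variance etc.)."""


class CompositionError(ValidationError):
    """A requested class ratio cannot be realized with the data at hand."""


class TrainingError(CytofeatError):
    """The classifier could not be fit (e.g. a single-class training set)."""
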