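"""Exception hierarchy shared across the pipeline."""


class MilintvError(Exception):
    """Base class for all package errors."""


class TranscriptFormatError(MilintvError):
    """A transcript table is missing a required column or is otherwise unreadable."""


class RowParseError(MilintvError):
    """A single transcript row could not be parsed (carries the 1-based line number)."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class EmptyInputError(MilintvError):
    """An operation received an empty utterance/instance sequence."""


class EmptyBagError(MilintvError):
    """A bag with zero instances was constructed or evaluated."""


class ScorerContractError(MilintvError):
    """A scorer returned a value outside [0, 1]."""


class AlignmentError(MilintvError):
    """Two scored bags do not refer to the same bag/instances."""


class DegenerateTrainingError(MilintvError):
    """Scorer training data contains a single class."""


class ParameterError(MilintvError):
    """A hyperparameter or option is out of its valid range."""


class ClassCoverageError(MilintvError):
    """An evaluation requires both classes but only one is present."""


class EmptyEvaluationError(MilintvError):
    """All confusion counts are zero."""


class ConfigError(MilintvError):
    """Invalid generator or pipeline configuration."""
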