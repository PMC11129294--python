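"""Typed exceptions raised across the package."""


class QeqnetError(Exception):
    """Base class for all package errors."""


class ParseError(QeqnetError):
    """A molecule record could not be parsed; names the offending record."""


class UnsupportedElementError(QeqnetError):
    """An element lies outside the featurization vocabulary.

    One-hot element encoding cannot generalize to unseen elements, so
    out-of-vocabulary atoms are rejected up front rather than silently
    mis-featurized.
    """


class DisconnectedMoleculeError(QeqnetError):
    """Multi-fragment input: the per-molecule total-charge constraint is
    ambiguous for disconnected records, so they are rejected."""


class MoleculeValidationError(QeqnetError):
    """Bond list violates the molecule invariants (bad indices, duplicates)."""


class DimensionError(QeqnetError):
    """Array shape mismatch between operands."""


class BatchError(QeqnetError):
    """Invalid batching request (e.g. empty graph sequence)."""


class NumericalError(QeqnetError):
    """A non-finite value appeared in a numerical pipeline."""


class HardnessError(QeqnetError):
    """A hardness value fell at or below the positivity guard; the
    charge-equilibration objective would not be strictly convex."""


class EmptyMoleculeError(QeqnetError):
    """An operation that needs at least one atom received none."""


class FormatError(QeqnetError):
    """Unknown or unsupported file format."""


class CheckpointError(QeqnetError):
    """Model checkpoint unreadable or incompatible (e.g. featurization
    version mismatch)."""


class TrainingDivergedError(QeqnetError):
    """Loss became non-finite during optimization."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
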