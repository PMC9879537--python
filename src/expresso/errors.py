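"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`ExpressoError`
so callers (and the CLI) can distinguish user/data problems from bugs.
"""


class ExpressoError(Exception):
    """Base class for all errors raised by expresso."""


class FormatError(ExpressoError, ValueError):
    """Malformed input file (ragged rows, negative counts, bad columns ...)."""


class ConfigurationError(ExpressoError, ValueError):
    """Invalid configuration value or missing required column/field."""


class GeneLookupError(ExpressoError, KeyError):
    """A gene ID could not be resolved in the expression map it should live in."""


class SamplingError(ExpressoError, ValueError):
    """Requested more random pairs than the candidate pool holds."""


class PartitionError(ExpressoError, ValueError):
    """Cross-validation fold partition cannot be constructed."""


class TrainingError(ExpressoError, ValueError):
    """Classifier training impossible (single class, empty set, ...)."""


class CoverageError(ExpressoError, ValueError):
    """An orthogroup pair lacks an expression score."""


class NormalizationError(ExpressoError, ValueError):
    """Size factors cannot be computed (no gene expressed in every sample)."""


class MatchingError(ExpressoError, ValueError):
    """A sample label referenced by a matching is absent from its map."""


class EvaluationError(ExpressoError, ValueError):
    """Metric undefined for the given inputs (e.g. single-class labels)."""
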