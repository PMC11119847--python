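"""Exception hierarchy shared across the package."""


class QuboDockError(Exception):
    """Base class for all package errors."""


class FormatError(QuboDockError):
    """Input could not be parsed (bad SMILES/SDF/MOL, missing property)."""


class ValidationError(QuboDockError):
    """Input parsed but violates a contract (disconnected graph, bad vector)."""


class ConfigurationError(QuboDockError):
    """Inconsistent configuration (non-divisible box edge, bad weights)."""


class ParameterizationError(QuboDockError):
    """A force field could not assign parameters to an atom."""


class GenerationError(QuboDockError):
    """The synthetic generator could not satisfy its guarantees."""
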