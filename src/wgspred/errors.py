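"""Exception hierarchy shared across the pipeline."""


class WgspredError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WgspredError):
    """A parameter value is outside its admissible range."""


class InfeasibleDesignError(WgspredError):
    """A requested design cannot be realised with the given inputs."""


class IntegrityError(WgspredError):
    """An input violates a structural invariant (e.g. cyclic pedigree)."""


class DegenerateInputError(WgspredError):
    """Input carries no usable information (e.g. all-monomorphic mask)."""


class SchemaError(WgspredError):
    """Mismatched identifiers/columns between two structures."""


class ParseError(WgspredError):
    """A file could not be parsed; message carries location context."""
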