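"""Exception hierarchy shared across the package."""


class MothraError(Exception):
    """Base class for all package-specific errors."""


class UnknownTokenError(MothraError):
    """A substring of a SMILES string is not in the vocabulary.

    Carries the offending substring and its character position.
    """

    def __init__(self, substring: str, position: int, line: int | None = None):
        self.substring = substring
        self.position = position
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(
            f"unknown token {substring!r} at position {position}{where}"
        )


class EmptyCorpusError(MothraError):
    """Training corpus contains no usable SMILES lines."""


class PrefixContainsTerminatorError(MothraError):
    """A policy prefix already contains the end-of-sequence token."""


class DimensionMismatchError(MothraError):
    """Reward vectors of different dimension were compared."""


class ReferenceNotDominatedError(MothraError):
    """A front point lies below the hypervolume reference point."""


class NoExpandableTokenError(MothraError):
    """A search node has no remaining candidate child tokens."""


class DomainError(MothraError):
    """A scalar argument lies outside its documented domain."""


class EmptyLogError(MothraError):
    """A generation log with no records was passed to the metrics."""


class ConfigError(MothraError):
    """A run configuration file is malformed or has unknown keys."""


class AdapterError(MothraError):
    """An external objective adapter (docking engine, predictor) failed."""


class SpaceTooLargeError(MothraError):
    """A toy search space exceeds the exhaustive-enumeration cap."""


class CheckpointError(MothraError):
    """A policy checkpoint is inconsistent or does not match its vocabulary."""
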