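"""Exception hierarchy shared across the pipeline stages."""


class CdonBdError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CdonBdError, ValueError):
    """Malformed delimited-text input (ragged rows, non-numeric fields)."""


class ValidationError(CdonBdError, ValueError):
    """Input violates a documented contract (shapes, labels, duplicates)."""


class DegenerateSignalError(CdonBdError, ValueError):
    """A regional time series has zero variance; Pearson r is undefined."""


class StateError(CdonBdError, RuntimeError):
    """Operation applied to data in the wrong state (e.g. double Fisher-z)."""


class DivergenceError(CdonBdError, RuntimeError):
    """Training produced a non-finite loss; reduce the learning rate."""


class DegenerateCorpusError(CdonBdError, ValueError):
    """Walk corpus contains fewer than two distinct nodes."""


class UndefinedDistanceError(CdonBdError, ValueError):
    """Cosine distance requested against a zero-norm vector."""


class InfeasibleSpecError(CdonBdError, ValueError):
    """Synthetic cohort specification cannot yield a valid correlation matrix."""


class StratificationError(CdonBdError, ValueError):
    """Cross-validation fold would contain a single class."""
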