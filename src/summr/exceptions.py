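"""Exception hierarchy for summr."""


class SummrError(Exception):
    """Base class for all summr errors."""


class ConfigError(SummrError):
    """A configuration problem: missing column, missing file, bad mapping."""


class EmptyInputError(SummrError):
    """An input table or result set contained no usable rows."""


class ParameterError(SummrError, ValueError):
    """An argument violated a precondition (invalid fraction, size, range)."""


class HarmonizationError(SummrError):
    """Exposure and outcome studies could not be aligned at all."""


class MethodError(SummrError):
    """An estimator could not run (too few instruments, non-convergence,
    rank deficiency).  Carries diagnostics in ``args``."""
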