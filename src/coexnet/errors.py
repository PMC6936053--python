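"""Exception and warning types shared across the package."""


class CoexnetError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CoexnetError, ValueError):
    """A text input (expression table, GMT file) could not be parsed."""


class ValidationError(CoexnetError, ValueError):
    """An input violated a documented contract (duplicates, shape, range)."""


class CoexnetWarning(UserWarning):
    """Base class for warnings emitted by this package."""


class ZeroVarianceWarning(CoexnetWarning):
    """A gene had constant expression; its associations are degenerate."""


class FallbackThresholdWarning(CoexnetWarning):
    """No inflection point was found; a quantile fallback threshold was used."""
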