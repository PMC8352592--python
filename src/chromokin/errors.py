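"""Exception types shared across the package."""


class ChromokinError(Exception):
    """Base class for all package errors."""


class ValidationError(ChromokinError):
    """A specification or input object violates one of its invariants.

    The message always names the offending field.
    """


class AnalysisError(ChromokinError):
    """An analysis step received degenerate input (e.g. no bleach detected)."""
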