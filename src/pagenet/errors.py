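"""Exception types shared across the package."""


class PagenetError(Exception):
    """Base class for package errors."""


class FormatError(PagenetError):
    """A file or in-memory object violates a format contract."""


class InvalidConfigError(PagenetError, ValueError):
    """A configuration object violates its invariants."""


class DegenerateProfileError(PagenetError):
    """A fold-change profile has zero spread; Z-scores are undefined."""


class EmptyMergeError(PagenetError):
    """An ortholog merge retained no usable gene pairs."""
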