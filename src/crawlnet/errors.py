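"""Exception hierarchy shared across the package."""


class CrawlnetError(ValueError):
    """Base class for all crawlnet validation and contract errors."""


class FormatError(CrawlnetError):
    """A tabular input is missing required columns or is otherwise malformed."""


class ValidationError(CrawlnetError):
    """An input violates a documented invariant (negative counts, NaN, ...)."""


class EmptyInputError(CrawlnetError):
    """An operation received an empty collection where >=1 element is required."""


class AlignmentError(CrawlnetError):
    """Two containers that must share indexing do not."""


class DivergenceError(CrawlnetError):
    """A simulation or optimization produced non-finite state."""
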