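"""Exception hierarchy."""


class DbgmapError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DbgmapError):
    """A sequence file could not be parsed."""


class WalkError(DbgmapError):
    """A unitig walk contains a non-adjacent consecutive pair."""


class SearchLimitExceeded(DbgmapError):
    """The exhaustive search expanded more states than allowed."""
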