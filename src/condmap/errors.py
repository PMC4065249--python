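"""Exception hierarchy for condmap."""


class CondmapError(Exception):
    """Base class for all condmap errors."""


class FormatError(CondmapError):
    """A file does not conform to the expected layout."""


class DuplicateRecordError(FormatError):
    """The same (query, array, condition, replicate) key appears twice."""


class InsufficientDataError(CondmapError):
    """Too few observations for the requested computation."""


class DegenerateSpreadError(CondmapError):
    """A scale estimate is zero; standardization is undefined."""


class ConfigurationError(CondmapError):
    """Invalid parameter combination or missing required input."""
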