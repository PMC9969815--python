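"""Exception hierarchy.

All tool-specific failures derive from :class:`LdmxError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class LdmxError(Exception):
    """Base class for all ldmx errors."""


class FormatError(LdmxError):
    """An input file does not conform to its declared format."""


class VersionError(FormatError):
    """A container was written with an unsupported format version."""


class DataError(LdmxError):
    """Inputs are individually well-formed but mutually inconsistent,
    or a requested quantity is mathematically undefined."""


class ParameterError(LdmxError):
    """A parameter value is outside its legal range."""


class CapabilityError(LdmxError):
    """The container lacks the data required by the request
    (e.g. a MAF query against a container built without MAF)."""
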