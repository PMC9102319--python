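"""Exception hierarchy for depthmask.

All library errors derive from :class:`DepthMaskError` so callers can catch
one base class; the CLI maps them to exit code 1 (data errors) while usage
mistakes surface as exit code 2 through click.
"""


class DepthMaskError(Exception):
    """Base class for all depthmask errors."""


class FormatError(DepthMaskError):
    """A container file has a bad magic number, version or header field."""


class CorruptionError(DepthMaskError):
    """A container file is truncated or inconsistent with its header."""


class ContractError(DepthMaskError):
    """An operation was called with arguments violating its contract."""


class FixtureError(DepthMaskError):
    """A self-validating synthetic fixture failed its own property check."""
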