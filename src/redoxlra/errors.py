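"""Exception hierarchy shared by all modules.

The CLI maps these onto exit codes: validation-type failures exit 2,
I/O failures exit 3.
"""


class RedoxError(Exception):
    """Base class for all package errors."""


class ValidationError(RedoxError, ValueError):
    """Invalid argument, inconsistent data, or violated invariant."""


class ParseError(RedoxError, ValueError):
    """A file could not be parsed; message names the offending line."""


class StructuralError(RedoxError, ValueError):
    """Frames or records are individually valid but mutually inconsistent."""


class ContentError(RedoxError, ValueError):
    """A file parsed cleanly but lacks required content."""


class ClashError(ValidationError):
    """Two atoms are unphysically close; message names both atoms."""
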