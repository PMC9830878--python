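"""Exception hierarchy for the pipeline."""


class XylolinkError(Exception):
    """Base class for all package errors."""


class FormatError(XylolinkError):
    """A file does not conform to its declared format."""


class IntegrityError(XylolinkError):
    """A file parses but violates a data invariant (duplicates, dimension mismatch)."""


class StateError(XylolinkError):
    """An operation was applied to an object in the wrong state."""
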