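"""Exception hierarchy shared by all pipeline stages."""


class PrismError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PrismError):
    """A file does not conform to its declared format (malformed XML,
    missing mandatory element, unparsable table)."""


class IntegrityError(PrismError):
    """A file parses but violates a semantic invariant (duplicate pixel
    coordinates, duplicate region names, degenerate polygon)."""


class WorkflowError(PrismError):
    """A stage was invoked in a state that has no meaningful result
    (empty region list, empty mask, no annotations after FDR filtering)."""
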