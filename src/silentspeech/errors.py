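"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A domain object or argument violates one of its invariants."""


class CorpusIOError(IOError):
    """A corpus manifest or signal file could not be read or written."""
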