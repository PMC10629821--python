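"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A configuration or argument value violates its stated constraints."""


class StateError(RuntimeError):
    """An operation was invoked on an object in the wrong state."""


class FormatError(ValueError):
    """An input file or array does not have the expected layout."""
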