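"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """An argument violates an operation's contract (bad range, unknown id, ...)."""


class ConfigError(InputError):
    """A configuration object violates one of its invariants."""


class DegenerateInputError(InputError):
    """Input is formally valid but carries no usable signal (e.g. all-zero variances)."""
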