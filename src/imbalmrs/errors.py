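"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input value violates an operation's contract."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent."""


class FitError(RuntimeError):
    """A base learner could not be fitted (e.g. a degenerate weighted sample)."""
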