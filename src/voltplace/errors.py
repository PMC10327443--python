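"""Exception types shared across the package."""


class InvalidConfigError(ValueError):
    """A configuration value violates an invariant (non-positive rate, bad mode, ...)."""


class AnalysisError(RuntimeError):
    """An operation cannot produce a defined result on this input."""
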