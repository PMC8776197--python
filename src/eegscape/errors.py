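"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """An invalid or inconsistent configuration (unknown keys, missing signatures, bad montage)."""


class DataError(RuntimeError):
    """Unreadable, malformed or missing input data."""
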