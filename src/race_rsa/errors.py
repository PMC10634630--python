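class DataError(ValueError):
    """An input violates a documented precondition (bad labels, shapes, thresholds...)."""


class ConfigError(ValueError):
    """A run configuration is malformed: unknown keys, missing seeds, bad paths."""
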