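"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """A generator or analysis parameter is outside its valid domain."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate (e.g., zero total area)."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (overlapping phenotype panel, wrong caller set)."""
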