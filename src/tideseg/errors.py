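"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration value (kernel sizes, stage sets, weights...)."""


class ShapeError(ValueError):
    """Mismatched or incompatible array shapes."""


class InputError(ValueError):
    """Invalid input data (empty rasters, non-binary masks, wrong channels)."""
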