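"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter or configuration value is invalid or inconsistent."""


class FormatError(ValueError):
    """An input file does not match the expected plain-text format."""
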