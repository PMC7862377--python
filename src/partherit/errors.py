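"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or analysis configuration is internally inconsistent."""


class FormatError(IOError):
    """An on-disk file does not conform to its declared format."""


class EmptyPanelError(RuntimeError):
    """An operation produced or received a genotype panel with no SNPs."""


class NonIdentifiableError(RuntimeError):
    """A variance-component model whose components cannot be separated."""
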