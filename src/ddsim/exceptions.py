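"""Exception hierarchy for ddsim."""


class DDSimError(Exception):
    """Base class for all ddsim errors."""


class FormatError(DDSimError):
    """A file or table does not conform to the expected layout."""


class ConfigError(DDSimError):
    """An invalid configuration value was supplied."""


class UndefinedSimilarityError(DDSimError):
    """A similarity is mathematically undefined for the given input
    (zero-norm vector for cosine, two empty sets for Jaccard)."""


class UndefinedCorrelationError(DDSimError):
    """Pearson correlation is undefined (constant vector)."""
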