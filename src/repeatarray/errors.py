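"""Exception hierarchy for the repeatarray pipeline."""


class RepeatArrayError(Exception):
    """Base class for all pipeline errors."""


class PartitionError(RepeatArrayError):
    """Sequence length is not compatible with the declared repeat-unit length."""


class MetadataError(RepeatArrayError):
    """A sequence record has no entry in the sample table (or vice versa)."""


class ConfigError(RepeatArrayError):
    """An invalid configuration value (mask position, window, weight...)."""


class LengthError(RepeatArrayError):
    """Compared sequences or units have incompatible lengths."""


class TreeError(RepeatArrayError):
    """Distance matrix unsuitable for tree building, or unknown label."""


class PoolError(RepeatArrayError):
    """A repeat pool is empty or too small for the requested statistic."""
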