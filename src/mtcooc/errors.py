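"""Exception hierarchy for the co-occurrence pipeline."""


class MtcoocError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MtcoocError, ValueError):
    """Invalid run or simulation configuration."""


class AlignmentError(MtcoocError, ValueError):
    """Malformed alignment input (e.g. unequal record lengths)."""


class MetadataError(MtcoocError, ValueError):
    """Missing or invalid sample metadata."""


class GroupError(MtcoocError, ValueError):
    """Invalid or empty altitude group."""


class UndefinedAlleleError(MtcoocError, ValueError):
    """Co-occurrence frequency requested for an allele absent at a site."""


class DegenerateVarianceError(MtcoocError, ValueError):
    """Pooled proportion of 0 or 1 leaves the Z statistic undefined."""
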