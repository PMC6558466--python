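"""Exception hierarchy for grskit.

Every error raised deliberately by the package derives from :class:`GrsKitError`,
so callers (and the CLI) can distinguish data problems from genuine bugs.
"""


class GrsKitError(Exception):
    """Base class for all grskit errors."""


class CatalogError(GrsKitError):
    """Malformed or invalid SNP catalog (format, parse, or validation)."""


class GenotypeError(GrsKitError):
    """Malformed genotype input (VCF or dosage matrix)."""


class AlignmentError(GenotypeError):
    """Catalog and genotype alleles cannot be reconciled for a SNP."""


class AnalysisError(GrsKitError):
    """A statistical operation received degenerate or inconsistent input."""


class ConfigError(GrsKitError):
    """Invalid pipeline configuration."""
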