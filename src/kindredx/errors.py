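"""Exception hierarchy for kindredx."""


class KindredXError(Exception):
    """Base class for all kindredx errors."""


class ConfigurationError(KindredXError):
    """A required input, field, or setting is missing or inconsistent."""


class VcfParseError(KindredXError):
    """A VCF file could not be parsed into sample calls."""


class SampleNotFoundError(VcfParseError):
    """The requested sample is absent from a VCF."""


class DuplicateVariantError(KindredXError):
    """Two calls share the same (chrom, pos, ref, alt) key within one sample."""


class UndefinedStatisticError(KindredXError):
    """A statistic has no defined value for the given inputs (e.g. empty overlap)."""


class DomainError(KindredXError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class PanelIntegrityError(KindredXError):
    """A reference panel failed an integrity audit and was refused."""
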