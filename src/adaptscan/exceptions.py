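"""Exception hierarchy for adaptscan."""


class AdaptscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AdaptscanError):
    """Invalid experiment configuration or architecture."""


class ExtinctionError(AdaptscanError):
    """A replicate cannot produce the next generation (no seed parents)."""


class FormatError(AdaptscanError):
    """Malformed input file (VCF, 012 matrix, GFF3, ...)."""


class DegenerateFitError(AdaptscanError):
    """A model fit is undefined for the given data (e.g. zero trait variance)."""
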