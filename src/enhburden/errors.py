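"""Exception hierarchy shared across the pipeline."""


class EnhburdenError(Exception):
    """Base class for all package errors."""


class ConfigError(EnhburdenError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(EnhburdenError):
    """Invalid or unusable input data (CLI exit code 3)."""


class VcfParseError(DataError):
    """Malformed VCF input; message names the offending record when known."""


class EmptyCohortError(DataError):
    """No samples left (empty VCF, or QC removed everyone)."""


class FormatError(DataError):
    """Malformed tabular input (enhancer map, annotations, sample table)."""


class DuplicateKeyError(FormatError):
    """Duplicate annotation keys with conflicting values."""


class DegenerateSetError(DataError):
    """Variant set carries no usable variation for testing."""


class SeparationError(DataError):
    """Perfect separation on covariates in the unpenalised null fit."""
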