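"""Exception hierarchy shared by all secophen modules."""


class SecophenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SecophenError):
    """Bad user configuration: missing columns, unknown names, invalid options."""


class DataError(SecophenError):
    """Invalid values in user data (e.g. non-binary disease status)."""


class DegenerateGenotypeError(DataError):
    """Fewer than two occupied genotype levels: no association test is possible."""


class DesignError(SecophenError):
    """Rank-deficient or otherwise unusable design matrix."""


class SiteLookupError(SecophenError):
    """Requested variant not present in the genotype source."""


class UnsupportedSiteError(SecophenError):
    """Variant present but not usable (e.g. multiallelic in GT mode)."""


class ParameterError(SecophenError, ValueError):
    """Model or simulation parameter outside its valid domain."""


class CalibrationError(SecophenError):
    """Disease-intercept calibration failed to bracket the target rate."""


class FeasibilityError(SecophenError):
    """Sampling quotas unreachable within the configured draw budget."""
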