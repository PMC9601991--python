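"""Exception hierarchy for the orbias pipeline."""


class OrbiasError(Exception):
    """Base class for all orbias-specific errors."""


class DimensionError(OrbiasError):
    """Requested geometry does not fit the voxel grid."""


class MeasurementError(OrbiasError):
    """A measurement is undefined for the given input (e.g. empty slice)."""


class YViewRangeError(OrbiasError):
    """Y-view offset falls outside the fossa extent."""


class ZeroFossaAreaError(OrbiasError):
    """Occupation ratio undefined: fossa area is zero on the selected slice."""


class ConfigError(OrbiasError):
    """Invalid or inconsistent run configuration."""


class DataError(OrbiasError):
    """Malformed or missing input data."""
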