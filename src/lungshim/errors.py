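"""Exception hierarchy for the lungshim package."""


class LungshimError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(LungshimError):
    """Non-positive matrix size or field of view, or mismatched geometries."""


class ConfigurationError(LungshimError):
    """A configuration value is out of range or the request is infeasible."""


class DegenerateInputError(LungshimError):
    """An input image carries no usable information (e.g. constant)."""


class EmptyMaskError(LungshimError):
    """Segmentation or masking produced no voxels."""


class RankDeficientError(LungshimError):
    """The shim design matrix is rank deficient over the given mask."""

    def __init__(self, message: str, deficient_columns=None):
        super().__init__(message)
        self.deficient_columns = tuple(deficient_columns or ())


class ShimConfigParseError(LungshimError):
    """A shim configuration file is missing keys or has malformed lines."""

    def __init__(self, message: str, missing_keys=None, bad_lines=None):
        super().__init__(message)
        self.missing_keys = tuple(missing_keys or ())
        self.bad_lines = tuple(bad_lines or ())
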