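"""Exception hierarchy for connectome predictive modelling errors."""


class ConnPredictError(Exception):
    """Base class for all package-specific errors."""


class InvalidAtlasError(ConnPredictError):
    """Atlas is malformed: unassigned nodes, fewer than the required networks, ..."""


class InvalidInputError(ConnPredictError, ValueError):
    """A structural input (matrix, node count, ...) violates a precondition."""


class InvalidParameterError(ConnPredictError, ValueError):
    """A tuning parameter is outside its admissible range."""


class DegenerateInputError(ConnPredictError):
    """Input data are degenerate, e.g. a zero-variance node time series."""


class DegenerateTargetError(ConnPredictError):
    """The prediction target is constant and cannot be modelled."""


class InsufficientDataError(ConnPredictError):
    """Too few subjects (or maps) for the requested analysis."""


class NoFeaturesError(ConnPredictError):
    """Feature screening or selection retained no edges."""


class CollinearityError(ConnPredictError):
    """Covariate matrix is rank deficient."""


class IncompatibleMapsError(ConnPredictError):
    """Two weight maps differ in level or atlas and cannot be compared."""


class IncompatibleFeatureSpaceError(ConnPredictError):
    """External connectomes are not in the model's edge space (atlas mismatch)."""


class InvalidTargetError(ConnPredictError):
    """A target correlation structure cannot be repaired to a valid matrix."""


class SchemaError(ConnPredictError):
    """An on-disk table violates its documented column schema."""
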