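"""Exception hierarchy shared across the package."""


class ClutchKitError(Exception):
    """Base class for all clutchkit errors."""


class InvalidInputError(ClutchKitError, ValueError):
    """Malformed data: non-finite coordinates, bad phase labels, etc."""


class InvalidParameterError(ClutchKitError, ValueError):
    """A parameter is outside its valid range (e.g. negative tolerance)."""


class UndefinedAngleError(ClutchKitError, ValueError):
    """An angle is requested for a degenerate (zero-length) vector."""


class InsufficientEggsError(ClutchKitError, ValueError):
    """An operation needs more eggs than the observation contains."""


class PairingError(ClutchKitError, ValueError):
    """Host eggs cannot be matched one-to-one between two phases."""


class EmptyMaskError(ClutchKitError, ValueError):
    """A binary clutch mask has no foreground pixels."""


class FrameSizeError(ClutchKitError, ValueError):
    """An egg falls outside the raster frame during rendering."""


class PlacementError(ClutchKitError, RuntimeError):
    """Eggs could not be placed without overlap within the retry budget."""


class DegenerateTableError(ClutchKitError, ValueError):
    """A contingency table has a zero margin."""


class SingularDesignError(ClutchKitError, ValueError):
    """A design matrix is rank deficient."""


class ConfigurationError(ClutchKitError, ValueError):
    """A run configuration is invalid (e.g. an empty treatment group)."""
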