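"""Exception types shared across the pipeline stages."""


class HypertraitError(ValueError):
    """Base class for all domain errors raised by this package."""


class IncompatibleCubesError(HypertraitError):
    """Raw/dark/white cubes disagree in shape or wavelength grid."""


class InvalidMeasurementError(HypertraitError):
    """Fresh/dry weights violate physical constraints."""


class FusionError(HypertraitError):
    """VNIR+SWIR fusion would produce a non-monotone wavelength grid."""


class NoVegetationError(HypertraitError):
    """A vegetation mask is empty where plant pixels are required."""


class InsufficientTrainingError(HypertraitError):
    """Too few training pixels for the one-class segmentation model."""


class EmptyPlantError(HypertraitError):
    """Scene rendering was asked for a plant with zero leaf area."""


class UnsupportedModelError(HypertraitError):
    """A model without a coefficient vector was used where one is required."""


class GridMismatchError(HypertraitError):
    """Model and cube wavelength grids cannot be matched within tolerance."""


class InvalidSplitError(HypertraitError):
    """A replicate-based train/validation split is empty or exhaustive."""
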