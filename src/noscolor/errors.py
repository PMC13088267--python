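"""Exception hierarchy shared by the package."""


class NoscolorError(Exception):
    """Base class for all package-specific errors."""


class InputError(NoscolorError, ValueError):
    """Invalid argument values (shapes, signs, missing classes, ...)."""


class WavelengthRangeError(NoscolorError, ValueError):
    """A wavelength was requested outside a dispersion table's span."""


class UndefinedChromaticityError(NoscolorError, ZeroDivisionError):
    """Chromaticity requested for an all-zero tristimulus."""


class IncompatibleGridError(NoscolorError, ValueError):
    """Two density grids do not share identical axes."""


class UndefinedMetricError(NoscolorError, ArithmeticError):
    """A statistic's denominator vanished (e.g. kappa with Pe = 1)."""


class ThresholdNotReachedError(NoscolorError, RuntimeError):
    """A perturbation scan could not reach the requested colour difference."""


class CapacityError(NoscolorError, ValueError):
    """More tiles/regions requested than the rendered area can hold."""
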