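"""Exception hierarchy shared across the package."""


class BmiRadarError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(BmiRadarError, ValueError):
    """Scan-geometry configuration violates a physical or structural constraint."""


class InvalidArgumentError(BmiRadarError, ValueError):
    """An operation received an argument outside its domain (e.g. speed <= 0)."""


class UnsupportedGridError(BmiRadarError, ValueError):
    """Frequency or time grid is not uniformly spaced / strictly increasing."""


class IncompatibleScanError(BmiRadarError, ValueError):
    """Two scans (or a scan and a config) disagree in shape or axes."""


class InvalidInputError(BmiRadarError, ValueError):
    """Beamformer input is structurally invalid (e.g. empty sinogram)."""


class InvalidImageError(BmiRadarError, ValueError):
    """Image violates the non-negativity contract of the forward model."""


class InvalidDataError(BmiRadarError, ValueError):
    """Measured data violate the non-negativity contract of the iterative update."""


class InvalidPhantomError(BmiRadarError, ValueError):
    """Phantom specification is inconsistent (scatterer outside the breast, ...)."""


class FormatError(BmiRadarError, ValueError):
    """A sinogram/image file could not be parsed; message locates the defect."""
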