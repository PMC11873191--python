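"""Exception hierarchy for the rootpheno pipeline."""


class RootPhenoError(Exception):
    """Base class for all rootpheno errors."""


class InvalidArgumentError(RootPhenoError, ValueError):
    """A parameter violated its precondition (e.g. even kernel size)."""


class FormatError(RootPhenoError):
    """Unsupported image layout or channel count."""


class DegenerateHistogramError(RootPhenoError):
    """Automatic thresholding received a constant (single-level) image."""


class DegenerateCalibrationError(RootPhenoError):
    """Ruler calibration received coincident points."""


class UndefinedTraitError(RootPhenoError):
    """A trait is undefined for the given input (e.g. empty skeleton)."""


class InternalConsistencyError(RootPhenoError):
    """A pipeline invariant was violated (e.g. skeleton pixel outside mask)."""


class InvalidFixtureError(RootPhenoError):
    """A synthetic phantom specification is unusable (overlap, edge contact)."""


class EmptyInputError(RootPhenoError):
    """A batch run found no readable input images."""
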