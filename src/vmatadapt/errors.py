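"""Exception hierarchy for plan adaptation.

Every guarded failure (unknown MLC model, malformed plan, aperture
violation, ...) raises a subclass of :class:`VMATAdaptError` so callers can
catch the package's errors without masking programming mistakes.
"""


class VMATAdaptError(Exception):
    """Base class for all errors raised by vmatadapt."""


class UnknownModelError(VMATAdaptError, ValueError):
    """An MLC model name is not one of the supported devices."""


class PlanFormatError(VMATAdaptError, ValueError):
    """A file is not a readable DICOM RT Plan."""


class UnsupportedDeviceError(VMATAdaptError, ValueError):
    """A beam's MLC does not match any supported model."""


class PlanIntegrityError(VMATAdaptError, ValueError):
    """Plan content violates a structural invariant (monotone meterset,
    opposing-leaf ordering, bank size)."""


class ApertureGuardError(PlanIntegrityError):
    """An aperture has an opposing-leaf overlap (bank A > bank B)."""


class GapViolationError(VMATAdaptError, ValueError):
    """An adapted leaf pair falls below the configured deliverable minimum gap."""


class CorrespondenceError(VMATAdaptError, ValueError):
    """The leaf correspondence cannot be built for a geometry pair."""


class RecipeError(VMATAdaptError, ValueError):
    """A synthetic arc recipe is inconsistent with the bank geometry."""


class MetricsError(VMATAdaptError, ValueError):
    """Dose-summary inputs violate the metric preconditions."""
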