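"""Named exceptions raised across the pipeline."""


class XenoventError(Exception):
    """Base class for all package-specific errors."""


class UnknownVariantError(XenoventError, ValueError):
    """An acquisition variant other than pre_fess / post_fess was requested."""


class TimeOutOfRangeError(XenoventError, ValueError):
    """A time lookup fell outside the protocol's [0, duration) span."""


class MissingKineticsError(XenoventError, KeyError):
    """A labeled sinus has no exchange-rate entry in the phantom spec."""


class GridTooSmallError(XenoventError, ValueError):
    """The voxel grid cannot host every anatomical region."""


class TraceFrameMismatchError(XenoventError, ValueError):
    """Concentration traces are not sampled on the protocol's frame clock."""


class SidecarError(XenoventError, IOError):
    """A series sidecar is missing, unreadable, or inconsistent."""


class ShapeMismatchError(XenoventError, ValueError):
    """Array shapes disagree where the pipeline requires them to align."""


class MissingChannelError(XenoventError, KeyError):
    """A required spectral channel is absent from the series."""


class EmptyBaselineError(XenoventError, ValueError):
    """The baseline window for temporal enhancement contains no frames."""


class MissingLabelError(XenoventError, KeyError):
    """A requested region label is absent from the label volume."""


class EmptyMaskError(XenoventError, ValueError):
    """An ROI mask selects no voxels."""


class InvalidReferenceError(XenoventError, ValueError):
    """The 100%-xenon reference enhancement is non-positive or undefined."""


class FitWindowError(XenoventError, ValueError):
    """A kinetic-fit window is outside the curve or holds < 3 frames."""


class ConfigError(XenoventError, ValueError):
    """A configuration file failed validation."""
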