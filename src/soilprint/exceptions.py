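"""Named exceptions raised across the package.

All are subclasses of :class:`SoilprintError` so callers can catch the
package's failures with a single except clause; the finer-grained classes
exist because distinct contract violations deserve distinct names.
"""


class SoilprintError(Exception):
    """Base class for all soilprint errors."""


class InvalidConfigError(SoilprintError, ValueError):
    """A configuration object violates one of its invariants."""


class RetentionWindowError(SoilprintError, ValueError):
    """A retention time falls outside the allowed analysis/run window."""


class NegativeAreaError(SoilprintError, ValueError):
    """A peak area was requested or observed that is not strictly positive."""


class EmptyGroupError(SoilprintError, ValueError):
    """A cohort design contains a group with no samples."""


class MissingVariableError(SoilprintError, KeyError):
    """A soil-property specification lacks a required variable."""


class ShortTraceError(SoilprintError, ValueError):
    """A chromatogram is too short for the requested operation."""


class NonMonotoneTimeError(SoilprintError, ValueError):
    """A chromatogram time axis is not strictly increasing."""


class EmptyDataError(SoilprintError, ValueError):
    """A data file contained no usable rows."""


class AnchorError(SoilprintError, ValueError):
    """Anchor selection could not find enough universal peaks."""


class NonMonotoneMapError(SoilprintError, ValueError):
    """A retention-time alignment map is not monotone."""


class ToleranceError(SoilprintError, ValueError):
    """A matching tolerance is non-positive or otherwise unusable."""


class NoCommonPeakError(SoilprintError, ValueError):
    """No peak cluster survived the presence threshold."""


class ConstantVectorError(SoilprintError, ValueError):
    """A vector is constant (or zero) where variation is required."""


class LengthMismatchError(SoilprintError, ValueError):
    """Two aligned sequences have different lengths or feature orders."""


class SingularCovarianceError(SoilprintError, ValueError):
    """The pooled covariance is singular and no regularization was allowed."""


class DegenerateDataError(SoilprintError, ValueError):
    """Data carry no variance where a test statistic needs some."""


class MissingStageInputError(SoilprintError, ValueError):
    """A pipeline stage was enabled without its required input."""
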