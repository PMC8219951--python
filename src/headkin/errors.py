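"""Exception hierarchy for the pipeline.

All validation failures raise :class:`HeadkinError` subclasses so the CLI can
map them to exit status 2 while genuine bugs surface as ordinary exceptions
(exit status 1).
"""


class HeadkinError(Exception):
    """Base class for all pipeline validation errors."""


class InvalidSpecError(HeadkinError):
    """A generator or filter specification violates its invariants."""


class UnfilterableError(HeadkinError):
    """Sampling rate too low for the requested channel frequency class."""


class AlignmentError(HeadkinError):
    """Triaxial channels do not share a common time grid."""


class NoPeakError(HeadkinError):
    """No candidate peak survived spike screening.

    Carries the candidate log so the rejection reasons are auditable.
    """

    def __init__(self, message, candidate_log=None):
        super().__init__(message)
        self.candidate_log = candidate_log or []


class NoRiseError(HeadkinError):
    """The trace never falls below the rise threshold before the peak."""


class UnboundedPulseError(HeadkinError):
    """The trace never falls below half-maximum on one side of the peak."""


class InsufficientDataError(HeadkinError):
    """Too few observations for the requested statistic."""


class DegenerateGroupError(HeadkinError):
    """Control sample has zero variance; single-case t is undefined."""


class UndefinedStatError(HeadkinError):
    """Statistic undefined for the given inputs (e.g. COV with mean <= 0)."""


class InvalidStainsError(HeadkinError):
    """Stain matrix is singular or otherwise unusable."""


class InvalidThresholdError(HeadkinError):
    """Threshold lies outside the channel's value range."""
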