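"""Exception hierarchy for mrdeye.

Measurement-stage failures map onto the cohort exclusion rules applied
downstream: an image on which no pupil can be found, for example, is the
"machine could not measure" case and is excluded under rule 5 rather than
crashing a batch run.
"""


class MrdeyeError(Exception):
    """Base class for all mrdeye errors."""


class ClosedApertureError(MrdeyeError):
    """Lid parabolas cross at the pupil column: the eye is rendered shut."""


class MaskFormatError(MrdeyeError):
    """A label image contains values outside the {0, 1, 2, 3} convention."""


class PupilNotFoundError(MrdeyeError):
    """No dark connected component qualifies as a pupil."""


class InsufficientBoundaryError(MrdeyeError):
    """Too few pupil boundary pixels to fit a circle (minimum 6)."""


class MarginNotFoundError(MrdeyeError):
    """No background run found above the pupil center column."""


class CalibrationError(MrdeyeError):
    """Reference-dot detection failed (zero or multiple candidates)."""

    def __init__(self, message: str, n_candidates: int = 0):
        super().__init__(message)
        self.n_candidates = n_candidates


class CohortError(MrdeyeError):
    """Malformed cohort table or unknown method/reference name."""
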