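"""Exception hierarchy for the pupil localization pipeline."""


class PupilLocError(Exception):
    """Base class for all pupilloc errors."""


class EmptyImage(PupilLocError):
    """The input image has zero pixels."""


class NoValleyFound(PupilLocError):
    """The smoothed gray histogram has no peak-then-valley structure."""


class EmptyProfile(PupilLocError):
    """A projection profile contains no foreground counts."""


class NoPupilCandidate(PupilLocError):
    """The grayscale stage produced no usable rough pupil region."""


class NoCandidateRegions(PupilLocError):
    """No connected component passes the minimum-area floor."""


class EmptyRegion(PupilLocError):
    """Moments requested for a region with no pixels."""


class ZeroMass(PupilLocError):
    """Zero-order moment is zero; centroid undefined."""


class EmptyEvaluation(PupilLocError):
    """Accuracy requested over an empty record list."""


class InvalidParams(PupilLocError):
    """Synthetic scene parameters violate their invariants."""
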