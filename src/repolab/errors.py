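"""Exception hierarchy for the repolarization pipeline.

Every stage raises a subclass of :class:`RepolabError`, so the cohort driver
can isolate per-subject failures without catching unrelated bugs.
"""


class RepolabError(Exception):
    """Base class for all pipeline errors."""


class IncompleteLeadSetError(RepolabError):
    """A required ECG lead is missing from the input."""


class UnsupportedFormatError(RepolabError):
    """The input file dialect cannot be parsed (e.g. non-uniform sampling)."""


class NoGroupLabelError(RepolabError):
    """The cohort table has no group-label column."""


class InvalidTimingError(RepolabError):
    """Synthetic wave timing is inconsistent (waves of adjacent beats overlap)."""


class InsufficientBeatsError(RepolabError):
    """Fewer than two heartbeats were detected in the recording."""


class NoBeatsError(RepolabError):
    """A beat-level operation received an empty beat list."""


class ZeroEnergyBeatError(RepolabError):
    """The beat matrix is identically zero; decomposition is undefined."""


class FlatTWaveError(RepolabError):
    """No T-wave candidate rises above the detection threshold."""


class DegenerateQrsLoopError(RepolabError):
    """No usable QRS loop vectors remain after energy thresholding."""


class DegenerateTVectorError(RepolabError):
    """The T-peak vector has zero norm; cosines are undefined."""


class DegenerateTLoopError(RepolabError):
    """Too many per-lead T-wave reconstruction vectors have zero norm."""


class NoTDownslopeError(RepolabError):
    """The T wave has no descending limb; the tangent method cannot apply."""


class InvalidRRError(RepolabError):
    """A non-positive RR interval was supplied for rate correction."""


class EmptyGroupError(RepolabError):
    """A summary statistic was requested for an empty group."""


class InvalidReferenceError(RepolabError):
    """The reference SD for the abnormality rule is not positive."""


class CollinearCovariatesError(RepolabError):
    """The linear-model design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear covariates: {', '.join(self.columns)}")


class NoUsableSubjectsError(RepolabError):
    """Every subject in the cohort failed quality control."""
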