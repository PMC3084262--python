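"""Exception hierarchy for corecruit.

Every contract violation raises a subclass of :class:`CorecruitError` so
callers can catch package errors without catching unrelated exceptions.
"""


class CorecruitError(Exception):
    """Base class for all corecruit errors."""


# --- synthetic data -------------------------------------------------------

class InvalidConfigError(CorecruitError):
    """Generator configuration violates a precondition."""


class UnknownFactorError(CorecruitError):
    """A factor name was referenced that is not part of the dataset."""


class UnknownRegionError(CorecruitError):
    """A region id was referenced that is not part of the dataset."""


class RegionTooShortError(CorecruitError):
    """A region is shorter than the motif that should be planted in it."""


# --- peak calling ---------------------------------------------------------

class DegenerateReplicateError(CorecruitError):
    """A replicate has zero variance and cannot be standardized."""


class DegenerateProfileError(CorecruitError):
    """A profile is constant; no background distribution can be fitted."""


class EmptyInputError(CorecruitError):
    """An operation received an empty input where data is required."""


class MissingMockCoverageError(CorecruitError):
    """A peak's representative element is absent from the mock profile."""


# --- co-occupancy ---------------------------------------------------------

class EmptyJoinError(CorecruitError):
    """Targets and the cofactor p-value table share no regions."""


class DegenerateRegressorError(CorecruitError):
    """The regressor is constant; the regression is undefined."""


class UnscalableProfileError(CorecruitError):
    """A profile has zero mean over the bound regions and cannot be scaled."""


class InsufficientGroupError(CorecruitError):
    """A group has too few members for the requested test."""


class EmptyGroupError(CorecruitError):
    """A comparison group contains no mapped genes."""


class InsufficientGenesError(CorecruitError):
    """Fewer mapped genes than requested bins."""


# --- recruiter screen -----------------------------------------------------

class InvalidPWMError(CorecruitError):
    """A position weight matrix fails validation."""


class EmptyDenominatorError(CorecruitError):
    """Sensitivity requested against an empty target set."""


class DegeneratePanelError(CorecruitError):
    """Fewer than two non-missing scores; percent ranks are undefined."""


# --- regression -----------------------------------------------------------

class UnimputableColumnError(CorecruitError):
    """A column has too few observed values to impute from."""


class CollinearityError(CorecruitError):
    """The design matrix is singular; names the offending columns."""


class NonNestedError(CorecruitError):
    """Model comparison requested for non-nested models."""


class MissingRecruiterError(CorecruitError):
    """Prediction requested without a column for an included recruiter."""


class EmptyModelError(CorecruitError):
    """Every recruiter was removed; no model remains."""
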