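"""Exception hierarchy.

All package errors derive from :class:`BHTreeSimError` so callers can catch
one base class; the leaf classes are named after the failure they signal.
"""


class BHTreeSimError(Exception):
    """Base class for all errors raised by bhtreesim."""


class SpecParseError(BHTreeSimError):
    """A waiting-time specification string could not be parsed."""


class UnknownFamilyError(SpecParseError):
    """The generator name of a spec string is not recognized."""


class SpecArityError(SpecParseError):
    """A spec string has too few or too many parameters."""


class ParameterDomainError(SpecParseError):
    """A spec parameter is outside the domain of its distribution family."""


class DrawError(BHTreeSimError):
    """A waiting-time draw could not be produced (bad factor, non-finite value)."""


class ZeroWaitError(DrawError):
    """A spec kept producing non-positive waiting times after the resample cap."""


class EngineLimitError(BHTreeSimError):
    """The event loop exceeded its configured lineage-count safety cap."""


class RetryCapExceededError(BHTreeSimError):
    """Taxon-conditioned simulation failed to reach the target count within the retry cap."""

    def __init__(self, message: str, attempts: int = 0):
        super().__init__(message)
        self.attempts = attempts


class AllExtinctError(BHTreeSimError):
    """Every replicate of a batch went extinct; no tree statistics available."""


class TreeStructureError(BHTreeSimError):
    """Lineage records or node tables are internally inconsistent."""


class NewickParseError(BHTreeSimError):
    """A Newick string could not be parsed."""


class DuplicateLabelError(BHTreeSimError):
    """A tree contains duplicate tip labels."""


class SamplingError(BHTreeSimError):
    """Incomplete-sampling request cannot be satisfied on this tree."""
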