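"""Exception hierarchy for diallelkit.

All package errors derive from :class:`DiallelError` so callers can catch
one base class; the subclasses mirror the kinds of failure a diallel
analysis can hit (malformed files, impossible counts, broken designs,
degenerate estimates, unknown fixtures).
"""


class DiallelError(Exception):
    """Base class for all diallelkit errors."""


class FormatError(DiallelError):
    """A file does not conform to the expected CSV schema."""


class IntegrityError(DiallelError):
    """Data violate a logical constraint (counts, duplicates, ranges)."""


class DesignError(DiallelError):
    """The mating/trial design cannot support the requested analysis."""


class EstimationError(DiallelError):
    """An estimate is undefined (zero variance, non-positive denominator)."""


class FixtureLookupError(DiallelError, KeyError):
    """Unknown packaged fixture or parent identifier."""
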