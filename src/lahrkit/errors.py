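"""Exception hierarchy for lahrkit.

Every error raised by the library derives from :class:`LahrkitError`, so
callers (and the CLI) can catch one base class.
"""


class LahrkitError(Exception):
    """Base class for all lahrkit errors."""


class AlphabetError(LahrkitError):
    """A sequence contains characters outside the permitted alphabet."""


class ReferenceMismatchError(LahrkitError):
    """An edit's expected reference base(s) do not match the locus."""


class EditConflictError(LahrkitError):
    """Two edits overlap the same locus positions."""


class ParameterError(LahrkitError):
    """A parameter value is outside its allowed set or range."""


class PlacementError(LahrkitError):
    """An edit or feature falls outside the interval a design requires."""


class OverhangEditError(PlacementError):
    """The desired edit falls inside the sticky-end overhang.

    A mismatched overhang reduces repair efficiency, so this is rejected
    unless explicitly overridden.
    """


class LigationIncompatibleError(LahrkitError):
    """Sticky ends are not complementary; ligation cannot proceed."""


class AnnotationError(LahrkitError):
    """A CDS annotation required for codon-aware design is missing or
    does not cover the region of interest."""


class DisruptionModeError(ParameterError):
    """Simultaneous PAM + seed disruption was requested.

    Disrupting both abolishes the re-cut-protection benefit, so the
    combination is unrepresentable by design.
    """


class NoSiteError(LahrkitError):
    """No nuclease site (or site pair) satisfies the geometric constraints."""


class OrientationError(LahrkitError):
    """Insert overhangs are identical or mutually reverse-complementary,
    so the insert orientation is not enforced by ligation."""


class SimulationSpecError(LahrkitError):
    """A synthetic-fixture specification is invalid or infeasible."""


class EmptyInputError(LahrkitError):
    """An operation received an empty input it cannot act on."""
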