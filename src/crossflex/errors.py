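"""Exception hierarchy for crossflex.

All package errors derive from :class:`CrossflexError` so callers (and the
CLI) can distinguish input problems from bugs.
"""


class CrossflexError(Exception):
    """Base class for all crossflex errors."""


class FormatError(CrossflexError):
    """A file could not be parsed in its declared format."""


class EmptyStructureError(CrossflexError):
    """A structure file yielded zero atoms."""


class TopologyError(CrossflexError):
    """A trajectory frame does not match its topology."""


class EmptySelectionError(CrossflexError):
    """A selection resolved to zero atoms where atoms are required."""


class CorrespondenceError(CrossflexError):
    """Two coordinate sets that must correspond atom-by-atom do not."""


class NoCommonAtomsError(CorrespondenceError):
    """Atom matching between two structures found no shared atoms."""


class DegenerateGeometryError(CrossflexError):
    """Too few or collinear points: a rigid fit is not determined."""


class SpecError(CrossflexError):
    """Invalid parameters for a synthetic-trajectory specification."""


class DesignError(CrossflexError):
    """A study does not have the required 2x2 liganded/unliganded design."""
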