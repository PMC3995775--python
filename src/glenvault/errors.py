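"""Exception hierarchy for glenvault.

All validation and degeneracy problems raise subclasses of
:class:`GlenvaultError` so callers (and the CLI) can distinguish bad input
from bugs.
"""


class GlenvaultError(Exception):
    """Base class for all glenvault errors."""


class InputError(GlenvaultError, ValueError):
    """Malformed or inconsistent user input (files, tables, parameters)."""


class DegenerateGeometryError(GlenvaultError, ValueError):
    """Landmark configuration that does not define the requested construct
    (collinear plane landmarks, coincident axis endpoints, zero-length
    glenoid line)."""


class MissingLandmarkError(GlenvaultError, ValueError):
    """A landmark required by the requested operation or variant is absent."""


class DegenerateTestError(GlenvaultError, ValueError):
    """A statistical test whose sampling distribution collapses
    (all paired differences zero, zero variance)."""


class UndefinedReliabilityError(GlenvaultError, ValueError):
    """An ICC is undefined because the rating table carries no variance."""
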