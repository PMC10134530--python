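"""Exception hierarchy.

Format errors are raised while parsing files; validation errors when a parsed
object violates a data-model invariant; capability errors when a request
exceeds the supported problem size.
"""


class WgdPhaseError(Exception):
    """Base class for all package errors."""


class FormatError(WgdPhaseError):
    """A file does not conform to its expected dialect."""


class ValidationError(WgdPhaseError):
    """A data-model invariant is violated."""


class CapabilityError(WgdPhaseError):
    """The request is outside the supported range (e.g. too many genomes)."""


class FitError(WgdPhaseError):
    """Optimization failed; carries the best-so-far result if available."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class DegenerateTreeError(WgdPhaseError):
    """A requested gene tree would have fewer than two tips."""
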