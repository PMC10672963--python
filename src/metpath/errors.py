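"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`MetPathError`
so the CLI can map validation problems to a single exit code.
"""


class MetPathError(Exception):
    """Base class for all errors raised by this package."""


class ModelFormatError(MetPathError):
    """A model file could not be parsed (bad SBML/JSON)."""


class ModelValidationError(MetPathError):
    """A parsed model violates a structural invariant (e.g. a reaction
    cites an undeclared metabolite)."""


class ExpressionError(MetPathError):
    """An expression table violates its invariants (non-positive fold
    change, duplicated gene id, missing columns)."""


class ConditionError(MetPathError):
    """A condition specification references unknown reactions or renders
    the model infeasible."""


class InfeasibleError(ConditionError):
    """The constrained flux problem admits no feasible flux."""


class UnboundedError(ConditionError):
    """The flux problem is unbounded; exchange reactions need bounds."""


class SolverError(MetPathError):
    """The numerical solver failed to reach the requested accuracy."""


class DecompositionError(MetPathError):
    """Elementary-mode decomposition failed; usually indicates a
    subnetwork that was not mass-balance closed."""
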