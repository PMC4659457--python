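"""Exception hierarchy.

``InputError`` covers unreadable or malformed inputs (CLI exit code 2);
``ValidationError`` covers inputs that parse but violate a contract
(CLI exit code 3).
"""


class GlycolinkError(Exception):
    """Base class for all package errors."""


class InputError(GlycolinkError):
    """A required input is missing, unreadable, or malformed."""

    exit_code = 2


class ValidationError(GlycolinkError):
    """An input parsed but violates a documented precondition."""

    exit_code = 3


class MissingChainError(InputError):
    """A chain required by the chain map is absent from the structure."""


class DuplicateResidueError(InputError):
    """Two residues share the same (chain, residue number)."""


class ChargeRuleError(ValidationError):
    """A residue name is not covered by the protonation rule set."""


class MissingAtomError(ValidationError):
    """A side-chain atom required by the distance criterion is absent."""


class EmptyWindowError(ValidationError):
    """An analysis window contains too few frames."""


class SeriesMismatchError(ValidationError):
    """Two energy series have incompatible frame spacing."""


class OffsetConflictError(ValidationError):
    """Dual-numbered residues of one chain type imply different offsets."""


class TelopeptideError(ValidationError):
    """A residue maps outside the triple-helical numbering range."""


class SyntheticSpecError(ValidationError):
    """A synthetic-structure directive is inconsistent or unsatisfiable."""
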