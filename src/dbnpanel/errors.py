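"""Exception hierarchy shared across the package."""


class DbnError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(DbnError):
    """The temporal graph violates an acyclicity or reference invariant."""


class ConfigurationError(DbnError):
    """A network is missing tables or a table does not match the structure."""


class InputError(DbnError):
    """User-supplied data, evidence, or query arguments are invalid."""


class ImpossibleEvidenceError(DbnError):
    """Evidence has probability numerically indistinguishable from zero.

    Raised only when the evidence log-probability falls below the hard
    floor (log 1e-300), which is distinguishable from ordinary underflow
    of individual factor entries.
    """


class ConstraintConflictError(DbnError):
    """Structure-learning constraints contradict each other."""
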