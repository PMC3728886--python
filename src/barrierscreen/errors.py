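"""Exception hierarchy shared across the package."""


class BarrierScreenError(Exception):
    """Base class for all package errors."""


class StructureError(BarrierScreenError):
    """Malformed or empty structure, unresolvable backbone, bad records."""


class SelectionError(BarrierScreenError):
    """An atom/residue selector resolved to zero or several atoms."""


class UnknownResidueError(BarrierScreenError):
    """A residue is not covered by the protonation rules and carries no
    declared charge."""


class CorrespondenceError(BarrierScreenError):
    """Two structures that must share an atom-by-atom correspondence do not."""


class DerivationError(BarrierScreenError):
    """A structure-derivation step (e.g. GE -> ES) found its preconditions
    violated, such as a missing covalent link."""


class ConfigurationError(BarrierScreenError):
    """Inconsistent pipeline configuration (e.g. constraints requested for a
    pathway that cannot use them, missing engine binary)."""


class EngineError(BarrierScreenError):
    """Engine produced a non-finite energy or otherwise failed internally."""


class ParseError(BarrierScreenError):
    """Engine output could not be interpreted."""


class GenerationError(BarrierScreenError):
    """Synthetic-fixture generation could not satisfy its geometric spec."""
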