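"""Exception and warning types shared across the package."""


class AbEnsembleError(Exception):
    """Base class for all package errors."""


class PDBParseError(AbEnsembleError):
    """A structure file could not be parsed."""


class ValidationError(AbEnsembleError, ValueError):
    """An input object violates a documented invariant."""


class CoverageError(AbEnsembleError):
    """A structure is missing residues or atoms required by a region."""


class DegeneracyError(AbEnsembleError, ValueError):
    """Too few points (or a degenerate configuration) for a superposition."""


class EmptyResidueError(AbEnsembleError, ValueError):
    """A residue holds no atoms."""


class UndefinedMetricError(AbEnsembleError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero native contacts)."""


class PlacementError(AbEnsembleError, RuntimeError):
    """A fixture generator could not realize the requested geometry."""


class DataError(AbEnsembleError, RuntimeError):
    """A pipeline stage produced no usable output (e.g. everything filtered)."""


class DegeneracyWarning(UserWarning):
    """A superposition was computed from a degenerate (e.g. collinear) point set."""
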