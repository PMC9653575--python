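"""Exception hierarchy for petmtv.

All errors raised by the package derive from :class:`PetMtvError` so callers
can catch pipeline failures uniformly; each subclass also derives from the
closest built-in (``ValueError``/``IOError``) to stay idiomatic.
"""


class PetMtvError(Exception):
    """Base class for all petmtv errors."""


class FormatError(PetMtvError, ValueError):
    """An input file is not a supported volumetric format (e.g. not 3-D)."""


class GeometryError(PetMtvError, ValueError):
    """Grids mismatch or physical extents are incompatible."""


class GenerationError(PetMtvError, ValueError):
    """A phantom specification is inconsistent (e.g. overlapping structures)."""


class DegenerateInputError(PetMtvError, ValueError):
    """Input geometry defeats the algorithm (e.g. bladder above kidneys)."""


class EmptySpaceError(PetMtvError, ValueError):
    """No analyzable voxels remain in the analysis space."""


class ConfigurationError(PetMtvError, ValueError):
    """A model/config pairing is structurally incompatible."""
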