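"""Exception hierarchy.

All package-specific failures derive from :class:`PhoreseekError` so callers
can catch one base class at pipeline boundaries.
"""


class PhoreseekError(Exception):
    """Base class for all phoreseek errors."""


class FormulaParseError(PhoreseekError, ValueError):
    """A molecular-formula string could not be parsed."""


class MassTableError(PhoreseekError, KeyError):
    """An element is missing from the monoisotopic mass table."""


class StructureParseError(PhoreseekError, ValueError):
    """A structure file could not be parsed or is empty."""


class TrajectoryConsistencyError(PhoreseekError, ValueError):
    """MODEL blocks of a trajectory disagree in atom count or identity."""


class SchemaError(PhoreseekError, ValueError):
    """A JSON document does not conform to the expected schema."""


class SelectionError(PhoreseekError, ValueError):
    """An atom selection matched nothing (or everything)."""


class CapabilityError(PhoreseekError, ValueError):
    """The input lacks information required by the operation."""


class AlignmentError(PhoreseekError, ValueError):
    """Too few usable correspondences for a rigid overlay."""


class DegenerateAlignmentError(PhoreseekError, ValueError):
    """Matched points are collinear; the rigid transform is under-determined."""


class LabelingError(PhoreseekError, ValueError):
    """Screened molecules are missing activity labels."""


class DegenerateInputError(PhoreseekError, ValueError):
    """A statistic requires both classes / non-constant input."""


class DesignError(PhoreseekError, ValueError):
    """An experimental design is insufficient for the requested fit."""


class DegenerateFitError(PhoreseekError, ValueError):
    """Responses carry no variance; the regression is undefined."""


class NoAntagonismError(PhoreseekError, ValueError):
    """No dose ratio exceeds one; Schild regression is impossible."""


class GenerationError(PhoreseekError, RuntimeError):
    """A synthetic-data generator failed its own ground-truth self-check."""
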