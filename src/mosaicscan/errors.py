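"""Exception hierarchy.

Every failure mode the library reports deliberately maps onto one of these,
so the CLI can translate them into stable exit codes.
"""


class MosaicScanError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(MosaicScanError):
    """Rows of unequal length, or an empty alignment where one is required."""


class DuplicateNameError(MosaicScanError):
    """Two sequences share an identifier."""


class CharacterError(MosaicScanError):
    """A residue outside the nucleotide/IUPAC/gap set."""


class AlignmentFormatError(MosaicScanError):
    """Unparseable alignment or annotation file."""


class CoordinateError(MosaicScanError):
    """Annotation coordinates outside the alignment."""


class SelfComparisonError(MosaicScanError):
    """Pairwise operation called with i == j."""


class SizeError(MosaicScanError):
    """Too few sequences for the requested analysis."""


class InsufficientDataError(MosaicScanError):
    """Not enough informative sites / pairs for a statistic."""


class ConfigError(MosaicScanError):
    """Invalid configuration value or role assignment."""


class InfeasibleError(MosaicScanError):
    """Simulation or surgery request that cannot be satisfied."""
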