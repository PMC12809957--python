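"""Exception types shared across the package."""


class FlockdivError(Exception):
    """Base class for all package-specific errors."""


class PedigreeError(FlockdivError, ValueError):
    """Invalid pedigree structure or contents."""


class CycleError(PedigreeError):
    """The parent graph contains a cycle."""


class SexConflictError(PedigreeError):
    """An identifier is used both as a sire and as a dam."""


class GenotypeError(FlockdivError, ValueError):
    """Invalid genotype data or file format."""


class QcStageError(FlockdivError, RuntimeError):
    """A quality-control stage produced an empty dataset."""


class AnalysisError(FlockdivError, RuntimeError):
    """An estimator received inputs it cannot handle."""
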