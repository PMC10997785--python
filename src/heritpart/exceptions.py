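"""Exception hierarchy used across the package."""


class HeritpartError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HeritpartError, ValueError):
    """A file does not conform to its declared on-disk format."""


class EmptyPanelError(HeritpartError, ValueError):
    """A filtering step removed every SNP from the panel."""


class PedigreeError(HeritpartError, ValueError):
    """A pedigree violates structural requirements (cycles, unknown parents)."""


class MonomorphicSNPError(HeritpartError, ValueError):
    """A monomorphic SNP was passed to an estimator that divides by 2p(1-p)."""


class RegionTooSparseError(HeritpartError, ValueError):
    """Fewer SNPs than the minimum allowed remain in a genomic region."""


class AlignmentError(HeritpartError, ValueError):
    """Sample id sets of phenotypes and covariance matrices do not line up."""


class NumericalError(HeritpartError, RuntimeError):
    """A covariance matrix became numerically non-positive-definite."""
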