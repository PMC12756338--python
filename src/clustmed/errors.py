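"""Exception hierarchy for clustmed.

Estimation-level failures (rank deficiency, non-convergence) are
distinguished from data-level failures so that the bootstrap can count
the former per replicate without masking genuine input errors.
"""


class ClustmedError(Exception):
    """Base class for all clustmed errors."""


class ConfigError(ClustmedError, ValueError):
    """Invalid simulation or run configuration."""


class GenotypeError(ClustmedError, ValueError):
    """Malformed or non-biallelic SNP genotype."""


class AmbiguousHaplotypeError(GenotypeError):
    """The SNP pair cannot be resolved into defined APOE alleles.

    Raised for the undefined haplotype rs7412=T with rs429358=C, and for
    double-heterozygous genotypes whose phase (and hence diplotype) is
    ambiguous.
    """


class MediatorValueError(ClustmedError, ValueError):
    """Nonpositive or zero-variance mediator column."""


class EmptySampleError(ClustmedError, ValueError):
    """Analysis sample is empty after exclusions."""


class EstimationError(ClustmedError):
    """Base for model-fitting failures (countable in the bootstrap)."""


class RankDeficiencyError(EstimationError):
    """Design matrix is not full column rank."""


class SingleClusterError(EstimationError):
    """Fewer than two clusters: cluster-robust inference undefined."""


class ConvergenceError(EstimationError):
    """Iterative GEE solver failed to converge."""


class MediationError(ClustmedError, ValueError):
    """Mediator/outcome fit mismatch in the effect decomposition."""


class BootstrapError(ClustmedError, RuntimeError):
    """Too many bootstrap replicates failed to estimate."""


class SelectionError(ClustmedError, ValueError):
    """Stepwise selection could not estimate a candidate model."""
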