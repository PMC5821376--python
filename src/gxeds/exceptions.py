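"""Exception types raised across the package."""


class GxedsError(Exception):
    """Base class for package-specific errors."""


class EmptySNPError(GxedsError):
    """A SNP has no called genotypes (all missing)."""


class MonomorphicLocusError(GxedsError):
    """Linkage disequilibrium is undefined because a locus has a fixed allele.

    Raised instead of returning zero so that "no variation" is never
    confused with "no association".
    """


class SingularDesignError(GxedsError):
    """The regression design matrix is rank deficient.

    The message names the first offending column.
    """


class NoInteractionError(GxedsError):
    """An index requiring a non-zero interaction coefficient was requested
    from a fit with b3 = 0 (parallel lines never cross)."""


class SchemaError(GxedsError):
    """An input table does not provide the columns an analysis plan needs."""
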