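"""Exception hierarchy shared across the package.

All errors derive from :class:`NeurotypError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
failure modes of the analysis (bad schema, degenerate signals, too few
subjects, rank deficiency, ...).
"""


class NeurotypError(Exception):
    """Base class for all package errors."""


class SchemaError(NeurotypError, ValueError):
    """Input files or tables violate the expected layout."""


class DegenerateSignalError(NeurotypError, ValueError):
    """A signal (or variable) is constant where a correlation is required."""


class InsufficientDataError(NeurotypError, ValueError):
    """Too few subjects/observations for the requested computation."""


class RankDeficiencyError(NeurotypError, ValueError):
    """A matrix is rank deficient where full rank is required (e.g. CCA
    with more features than observations)."""


class CollinearityError(NeurotypError, ValueError):
    """Covariate matrix is rank deficient."""


class MissingCovariateError(NeurotypError, KeyError):
    """A required covariate (e.g. age) is absent."""
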