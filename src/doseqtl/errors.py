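"""Exception types raised across the pipeline.

All inherit from :class:`DoseQtlError` (itself a ``ValueError``) so callers
can catch pipeline problems with a single except clause while still getting
ordinary ValueError semantics.
"""


class DoseQtlError(ValueError):
    """Base class for all doseqtl errors."""


class InvalidParameterError(DoseQtlError):
    """A numeric or structural parameter is outside its allowed range."""


class ShapeMismatchError(DoseQtlError):
    """Two objects that must be dimension-aligned are not."""


class MissingControlError(DoseQtlError):
    """Drug-plate records lack a matching control-plate record."""

    def __init__(self, strains, message=None):
        self.strains = sorted(strains)
        super().__init__(
            message
            or f"no control record for strains: {', '.join(map(str, self.strains[:10]))}"
            + ("..." if len(self.strains) > 10 else "")
        )


class DegenerateRegressionError(DoseQtlError):
    """The regression covariate is constant; the fit is undefined."""


class InsufficientDataError(DoseQtlError):
    """Too few observations for the requested fit."""


class DegenerateLocusError(DoseQtlError):
    """A marker column is monomorphic; no effect is estimable."""


class CollinearityError(DoseQtlError):
    """The locus design matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"collinear locus columns: {', '.join(map(str, self.columns))}"
        )


class InsufficientReplicationError(DoseQtlError):
    """Replicate-based variance decomposition needs >= 2 replicates."""


class DegenerateParentsError(DoseQtlError):
    """Parent replicates have zero pooled variance."""


class AliasingError(DoseQtlError):
    """A factorial term is inestimable because of empty design cells."""


class NumericalConditioningError(DoseQtlError):
    """A matrix that must be positive semidefinite is not."""


class ParseError(DoseQtlError):
    """A data file could not be parsed; carries the 1-based line number."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MissingDoseError(DoseQtlError):
    """A configured dose is absent from the phenotype data."""
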