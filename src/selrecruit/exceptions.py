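"""Exception types raised across the package."""


class SelRecruitError(ValueError):
    """Base class for all package-specific errors."""


class InvalidDistributionError(SelRecruitError):
    """A supplied probability vector is not a valid distribution."""


class InvalidParameterError(SelRecruitError):
    """A generator or model parameter is outside its admissible range."""


class CodingError(SelRecruitError):
    """A binary covariate column contains values outside {-1, +1}."""


class DegenerateDensityError(SelRecruitError):
    """A continuous column has too little variation to estimate a density."""


class DegenerateScaleError(SelRecruitError):
    """Quantile anchors coincide; the affine rescaling is undefined."""


class DegenerateCovariateError(SelRecruitError):
    """A binary covariate takes a single value in the pool (p in {0, 1})."""


class DegenerateOutcomeError(SelRecruitError):
    """An outcome vector contains a single class (or zero events)."""


class InfeasibleStratumError(SelRecruitError):
    """A joint stratum is too small for balanced stratified sampling."""

    def __init__(self, message, stratum=None, available=None, required=None):
        super().__init__(message)
        self.stratum = stratum
        self.available = available
        self.required = required


class NotBracketedError(SelRecruitError):
    """A power curve never crosses the requested target level."""
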