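"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError and
ContractViolation -> 3, NumericalError -> 4.
"""


class DilucompError(Exception):
    """Base class for all package errors."""


class ContractViolation(DilucompError, ValueError):
    """An argument violated a documented precondition."""


class ConfigError(DilucompError):
    """Invalid or incomplete run configuration."""


class DataError(DilucompError):
    """Input data are structurally unusable (schema, empty, inconsistent)."""


class NumericalError(DilucompError, RuntimeError):
    """An integrator or solver failed; carries diagnostics, never silent NaN."""


class MortalityDomainError(ContractViolation):
    """Mortality rate at or above a species' growth rate where the
    re-parameterization is undefined; the message names the species."""


class DegenerateEquilibria(DilucompError):
    """The product of the two effective competition coefficients equals one:
    a continuum of fixed points exists and no discrete classification applies."""


class NoGrowthError(DataError):
    """An OD curve never reached the threshold density."""
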