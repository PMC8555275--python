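"""Exception hierarchy for tsmr."""


class TsmrError(Exception):
    """Base class for all tsmr errors."""


class ConfigurationError(TsmrError):
    """A table/column mapping or run configuration is unusable."""


class RowParseError(TsmrError):
    """A data row failed parsing or an invariant check.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class UnknownFixtureError(TsmrError, KeyError):
    """Requested packaged fixture does not exist."""


class EmptyInstrumentError(TsmrError):
    """No variant survived instrument selection; estimation needs >= 1."""


class UnresolvedPalindromeError(TsmrError):
    """A palindromic instrument has no usable proxy under proxy_required."""

    def __init__(self, rsids):
        self.rsids = list(rsids)
        super().__init__(
            "palindromic variant(s) without a usable proxy: " + ", ".join(self.rsids)
        )


class InsufficientVariantsError(TsmrError):
    """An estimator was given fewer variants than it requires."""


class DegenerateInstrumentError(TsmrError):
    """An instrument with zero exposure effect cannot form a Wald ratio."""


class CollinearityError(TsmrError):
    """No spread in exposure effects; regression with intercept is singular."""


class MissingFrequencyError(TsmrError):
    """An operation needs effect-allele frequency but the record lacks it."""


class InfeasiblePowerError(TsmrError):
    """Requested power cannot be reached for any effect size."""
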