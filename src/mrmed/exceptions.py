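"""Exception hierarchy shared across the package."""


class MRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRError):
    """A user-supplied option, column map or config file is unusable."""


class EmptyInputError(MRError):
    """An operation received (or produced) zero usable records."""


class EmptyInstrumentError(EmptyInputError):
    """No variant passed the instrument-selection threshold for a trait."""

    def __init__(self, trait_id: str, p_threshold: float):
        self.trait_id = trait_id
        self.p_threshold = p_threshold
        super().__init__(
            f"no variant for trait {trait_id!r} passes p < {p_threshold:g}"
        )


class MethodUnavailableError(MRError):
    """Too few variants for the requested estimator."""


class UnderdeterminedError(MRError):
    """Fewer variants than regression coefficients in MVMR."""


class CollinearityError(MRError):
    """Exposure beta columns are (numerically) collinear."""

    def __init__(self, pair: tuple[str, str]):
        self.pair = pair
        super().__init__(f"exposure columns {pair[0]!r} and {pair[1]!r} are collinear")
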