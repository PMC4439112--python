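"""Exception hierarchy shared across the package."""


class RipseedError(ValueError):
    """Base class for all validation and configuration errors."""


class AlphabetError(RipseedError):
    """A sequence contains a character outside the allowed alphabet."""

    def __init__(self, symbol: str, position: int, alphabet: str):
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"invalid {alphabet} symbol {symbol!r} at position {position} (1-based)"
        )


class BoundsError(RipseedError):
    """A window or coordinate lies outside the sequence it indexes."""


class ConfigurationError(RipseedError):
    """Inconsistent inputs: missing sample classes, bad config values."""


class InsufficientDataError(RipseedError):
    """Too few observations for the requested statistic."""


class UndefinedRatioError(RipseedError):
    """A relative frequency has a zero background denominator."""


class FormatError(RipseedError):
    """A file failed validation; message names file/line/field."""
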