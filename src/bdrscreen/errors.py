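"""Exception hierarchy for the bdrscreen pipeline."""


class BdrScreenError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(BdrScreenError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class FormatError(BdrScreenError, ValueError):
    """An input table violates its column/uniqueness contract."""


class DomainError(BdrScreenError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class MissingDataError(BdrScreenError, ValueError):
    """Required data (e.g. a spirometry maneuver) is absent."""


class EstimabilityError(BdrScreenError, ValueError):
    """A model term cannot be estimated (rank deficiency, zero SE, ...)."""
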