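"""Exception hierarchy for psakit."""


class PsakitError(Exception):
    """Base class for all psakit errors."""


class FormatError(PsakitError):
    """A file does not match the documented format (e.g. missing column)."""


class RecordValidationError(PsakitError):
    """An assessment or billing record violates an item-level invariant."""


class MissingItemError(PsakitError):
    """A scale or classifier input item is missing under the reject policy."""


class TreeSchemaError(PsakitError):
    """A tree specification violates the structural schema."""


class ClassificationError(PsakitError):
    """A record cannot be routed to a terminal node."""


class ConfigurationError(PsakitError):
    """Invalid engine, filter, or simulation configuration."""


class SimulationError(PsakitError):
    """The synthetic generator could not satisfy its constraints."""
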