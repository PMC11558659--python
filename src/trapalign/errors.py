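"""Exception hierarchy shared by all engines."""


class TrapalignError(Exception):
    """Base class for all library errors."""


class InputError(TrapalignError):
    """Invalid user-supplied data (bad alphabet, malformed FASTA, cyclic graph)."""


class ConfigError(TrapalignError):
    """Inconsistent engine parameters (e.g. block side not lanes x stripes)."""


class ResourceError(TrapalignError):
    """Input exceeds a size cap of the chosen engine."""


class LaneOverflowError(TrapalignError):
    """A difference value does not fit the configured lane width (int8 mode)."""


class StateError(TrapalignError):
    """Operation requested in an invalid state (e.g. traceback without a store)."""


class InternalError(TrapalignError):
    """Shape or bookkeeping inconsistency; indicates a bug, not bad input."""
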