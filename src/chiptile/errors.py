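"""Exception hierarchy for chiptile."""


class ChiptileError(Exception):
    """Base class for all chiptile errors."""


class ConfigurationError(ChiptileError, ValueError):
    """Invalid parameters, models or channel layouts."""


class ParseError(ChiptileError, ValueError):
    """Malformed input file; the message names the offending line."""


class PlacementError(ChiptileError, RuntimeError):
    """Site placement failed (genome too crowded for non-overlapping sites)."""


class GridMismatchError(ChiptileError, ValueError):
    """Two tracks/tables do not share the identical probe grid."""
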