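"""Exception hierarchy for diazosym.

All errors raised on bad user input derive from :class:`DiazosymError` so
callers (and the CLI) can distinguish validation problems (exit code 2)
from genuine bugs (exit code 1).
"""


class DiazosymError(Exception):
    """Base class for all diazosym errors."""


class DomainError(DiazosymError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class ConfigurationError(DiazosymError, ValueError):
    """Labeling/simulation configuration is internally inconsistent."""


class SaturationError(DiazosymError, ValueError):
    """Isotopic enrichment at or beyond the label source; rate undefined."""


class ValidationError(DiazosymError, ValueError):
    """A data table violates its schema (reported with row/column context)."""
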