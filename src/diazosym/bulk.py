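"""Bulk CO2- and N2-fixation rates from incubation endpoints.

Two-point (start/end) design: the particulate pool's atom fraction moves
from its t0 value toward the labeled source over the incubation, and the
rate is the same linear-incorporation estimator used per cell, applied
to the whole particulate pool, in nmol l^-1 d^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError, DomainError

__all__ = ["BulkEndpoint", "bulk_fixation_rate", "replicate_summary"]

UMOL_TO_NMOL = 1000.0


@dataclass(frozen=True)
class BulkEndpoint:
    """Endpoint measurement of one incubation bottle.

    ``a_pn_t0`` / ``a_pn_t`` are the atom fractions of the particulate
    pool (PN or PC) at the start and end; ``pn_conc`` its concentration
    in umol l^-1; ``t_days`` the incubation length.
    """

    a_pn_t0: float
    a_pn_t: float
    pn_conc: float  # umol l^-1
    t_days: float = 1.0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.pn_conc <= 0:
            raise DomainError(f"pn_conc must be > 0, got {self.pn_conc}")
        if self.t_days <= 0:
            raise DomainError(f"t_days must be > 0, got {self.t_days}")
        if not (0 <= self.a_pn_t0 < 1 and 0 <= self.a_pn_t < 1):
            raise DomainError("atom fractions must lie in [0, 1)")


def bulk_fixation_rate(e: BulkEndpoint, a_source: float) -> float:
    """Bulk fixation rate in nmol l^-1 d^-1.

    ((A_t - A_t0) / (A_source - A_t0)) * [PN] * 1000 / t.  Functionally
    identical to the single-cell estimator with the particulate pool as
    the "cell".
    """
    if a_source <= e.a_pn_t0:
        raise ConfigurationError(
            f"a_source ({a_source}) must exceed the initial particulate "
            f"atom fraction ({e.a_pn_t0})"
        )
    x = (e.a_pn_t - e.a_pn_t0) / (a_source - e.a_pn_t0)
    return x * e.pn_conc * UMOL_TO_NMOL / e.t_days


def replicate_summary(rates: list[float]) -> tuple[float, float, int]:
    """Mean, sample SD (ddof=1; NaN for a single replicate) and n."""
    if not rates:
        raise DomainError("need at least one replicate")
    n = len(rates)
    mean = sum(rates) / n
    if n == 1:
        return mean, math.nan, 1
    var = sum((r - mean) ** 2 for r in rates) / (n - 1)
    return mean, math.sqrt(var), n
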