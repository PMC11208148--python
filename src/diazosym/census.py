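"""Microscopy census counts -> abundances -> volumetric fixation rates.

Counts from filtered-seawater microscopy are small, so confidence
intervals use the exact (Garwood) Poisson construction rather than a
normal approximation.  Cellular rates (fmol cell^-1 d^-1) times
abundance (cells l^-1) give volumetric rates in nmol l^-1 d^-1, which
are expressed as percent of the bulk incubation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import DomainError

__all__ = [
    "AbundanceRecord",
    "VolumetricRate",
    "abundance_from_count",
    "trichome_cell_count",
    "volumetric_rate",
    "contribution_percent",
]

FMOL_TO_NMOL = 1e-6


@dataclass(frozen=True)
class AbundanceRecord:
    taxon: str
    count: int
    volume_l: float
    abundance_per_l: float
    ci_low: float  # exact Poisson 95% bound, per litre
    ci_high: float


@dataclass(frozen=True)
class VolumetricRate:
    rate_nmol_per_l_d: float
    contribution_percent: float


def poisson_ci(count: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) two-sided Poisson CI for an observed count."""
    if count < 0:
        raise DomainError(f"count must be >= 0, got {count}")
    alpha = 1.0 - conf
    low = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2.0, 2 * count) / 2.0
    high = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * (count + 1)) / 2.0
    return low, high


def abundance_from_count(
    count: int, volume_l: float, taxon: str = "", conf: float = 0.95
) -> AbundanceRecord:
    """Abundance per litre with an exact Poisson CI on the raw count."""
    if count < 0:
        raise DomainError(f"count must be >= 0, got {count}")
    if volume_l <= 0:
        raise DomainError(f"volume_l must be > 0, got {volume_l}")
    low, high = poisson_ci(count, conf)
    return AbundanceRecord(
        taxon=taxon,
        count=count,
        volume_l=volume_l,
        abundance_per_l=count / volume_l,
        ci_low=low / volume_l,
        ci_high=high / volume_l,
    )


def trichome_cell_count(
    total_trichome_length_um: float, mean_cell_length_um: float
) -> float:
    """Cell count of filamentous taxa: summed trichome length divided by
    the average cell length (real-valued)."""
    if mean_cell_length_um <= 0:
        raise DomainError(
            f"mean_cell_length_um must be > 0, got {mean_cell_length_um}"
        )
    if total_trichome_length_um < 0:
        raise DomainError("total trichome length must be >= 0")
    return total_trichome_length_um / mean_cell_length_um


def volumetric_rate(per_cell_rate_fmol_d: float, abundance_per_l: float) -> float:
    """Scale a per-cell (or per-symbiosis) rate to nmol l^-1 d^-1."""
    if per_cell_rate_fmol_d < 0 or abundance_per_l < 0:
        raise DomainError("rate and abundance must be >= 0")
    return per_cell_rate_fmol_d * abundance_per_l * FMOL_TO_NMOL


def contribution_percent(volumetric: float, bulk: float) -> float:
    """Percent of the bulk rate explained by one taxon's volumetric rate."""
    if bulk <= 0:
        raise DomainError(f"bulk rate must be > 0, got {bulk}")
    if volumetric < 0:
        raise DomainError("volumetric rate must be >= 0")
    return 100.0 * volumetric / bulk
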