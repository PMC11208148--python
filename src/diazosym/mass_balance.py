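"""Host-symbiont nitrogen and carbon partitioning for whole symbioses.

Each symbiosis is one diatom host plus its intracellular N2-fixing
symbionts.  Because the host carries no nitrogenase, any 15N excess in
the host compartment is attributed to nitrogen fixed by the symbionts
and transferred; whole-symbiosis N2 fixation is therefore the sum of the
symbiont-retained rates and the host-recovered rate.  The headline
statistics are

* ``transfer_fraction_n`` (phi) -- share of symbiosis-fixed N recovered
  in the host, phi = 1 - F_sym / F_total;
* ``amplification_n`` -- F_total / F_sym, how many times more nitrogen
  the symbionts fix than they retain for their own growth
  (amplification = 1/(1-phi) exactly);
* ``carbon_transfer_fraction`` (psi) -- share of total fixed carbon
  ending up in the (heterotrophic) symbionts, psi = F_sym_C / F_total_C;
* mass-balanced growth -- the growth rate of the symbiosis as a whole,
  from the carbon-content-weighted mean atom fraction of all members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .isotopes import (
    CellBiomass,
    Compartment,
    IsotopeMeasurement,
    LabelingConfig,
    fixation_rate,
    growth_rate,
    ratio_to_atom_fraction,
)

__all__ = [
    "SymbiosisRecord",
    "PartitionResult",
    "partition_nitrogen",
    "partition_carbon",
    "symbiosis_growth",
    "partition",
]


@dataclass(frozen=True)
class SymbiosisRecord:
    """One host cell and its symbionts, with per-cell biomass attached."""

    symbiosis_id: str
    host: tuple[IsotopeMeasurement, CellBiomass]
    symbionts: tuple[tuple[IsotopeMeasurement, CellBiomass], ...]

    def __post_init__(self) -> None:
        if not self.symbionts:
            raise ValidationError(
                f"symbiosis {self.symbiosis_id}: at least one symbiont required"
            )
        members = [self.host[0]] + [m for m, _ in self.symbionts]
        for m in members:
            if m.symbiosis_id != self.symbiosis_id:
                raise ValidationError(
                    f"ROI {m.roi_id} carries symbiosis_id {m.symbiosis_id!r}, "
                    f"expected {self.symbiosis_id!r}"
                )
        if self.host[0].compartment is not Compartment.HOST:
            raise ValidationError(
                f"symbiosis {self.symbiosis_id}: host slot holds a "
                f"{self.host[0].compartment.value} ROI"
            )
        for m, _ in self.symbionts:
            if m.compartment is not Compartment.SYMBIONT:
                raise ValidationError(
                    f"symbiosis {self.symbiosis_id}: symbiont slot holds a "
                    f"{m.compartment.value} ROI"
                )


@dataclass(frozen=True)
class PartitionResult:
    """Whole-symbiosis fixation, transfer and growth statistics.

    ``transfer_fraction_n``, ``carbon_transfer_fraction`` and
    ``amplification_n`` are NaN when their denominators vanish
    (no fixation detected); ``amplification_n`` is ``inf`` when the
    symbionts retained nothing (complete transfer).
    """

    symbiosis_id: str
    f_total_n: float  # fmol N / d, whole symbiosis
    f_sym_n: float  # fmol N / d retained by symbionts
    transfer_fraction_n: float
    amplification_n: float
    f_total_c: float  # fmol C / d, whole symbiosis
    carbon_transfer_fraction: float
    growth_host: float  # divisions / d
    growth_sym_mean: float  # divisions / d, mean over symbionts
    growth_symbiosis: float  # divisions / d, mass-balanced


def _n_rate(m: IsotopeMeasurement, b: CellBiomass, cfg: LabelingConfig) -> float:
    return fixation_rate(
        ratio_to_atom_fraction(m.ratio_n),
        cfg.a_nat_n,
        cfg.a_source_n,
        b.n_content_fmol,
        cfg.t_days,
    )


def _c_rate(m: IsotopeMeasurement, b: CellBiomass, cfg: LabelingConfig) -> float:
    return fixation_rate(
        ratio_to_atom_fraction(m.ratio_c),
        cfg.a_nat_c,
        cfg.a_source_c,
        b.c_content_fmol,
        cfg.t_days,
    )


def partition_nitrogen(
    s: SymbiosisRecord, cfg: LabelingConfig
) -> tuple[float, float, float, float]:
    """Partition fixed nitrogen between symbionts and host.

    Returns ``(f_total_n, f_sym_n, transfer_fraction_n, amplification_n)``
    in fmol N/d (rates) and dimensionless (fractions).  The host 15N
    excess is counted as transferred nitrogen; symbiont excess as
    retained nitrogen.
    """
    f_sym = sum(_n_rate(m, b, cfg) for m, b in s.symbionts)
    f_host = _n_rate(*s.host, cfg)
    f_total = f_sym + f_host
    if f_total > 0:
        phi = (f_total - f_sym) / f_total
    else:
        phi = math.nan
    if f_sym > 0:
        amp = f_total / f_sym
    elif f_total > 0:
        amp = math.inf  # complete transfer: nothing retained
    else:
        amp = math.nan
    return f_total, f_sym, phi, amp


def partition_carbon(
    s: SymbiosisRecord, cfg: LabelingConfig
) -> tuple[float, float]:
    """Partition fixed carbon between host and symbionts.

    Returns ``(f_total_c, carbon_transfer_fraction)``: total carbon
    fixation of the symbiosis (photosynthesis is the only carbon source,
    so symbiont 13C excess traces host-derived carbon) and the share of
    it recovered in the symbionts.
    """
    f_sym = sum(_c_rate(m, b, cfg) for m, b in s.symbionts)
    f_host = _c_rate(*s.host, cfg)
    f_total = f_host + f_sym
    psi = f_sym / f_total if f_total > 0 else math.nan
    return f_total, psi


def symbiosis_growth(s: SymbiosisRecord, cfg: LabelingConfig) -> float:
    """Mass-balanced carbon growth rate of the whole symbiosis.

    The combined atom fraction is the carbon-content-weighted mean over
    host and symbionts, then the single-cell growth estimator is applied
    to it.  Equals each member's growth rate when all members are equally
    enriched, and tends to the host rate as symbiont carbon vanishes.
    """
    members = [s.host, *s.symbionts]
    total_c = sum(b.c_content_fmol for _, b in members)
    a_combined = (
        sum(ratio_to_atom_fraction(m.ratio_c) * b.c_content_fmol for m, b in members)
        / total_c
    )
    return growth_rate(a_combined, cfg.a_nat_c, cfg.a_source_c, cfg.t_days)


def partition(s: SymbiosisRecord, cfg: LabelingConfig) -> PartitionResult:
    """All partition statistics for one symbiosis."""
    f_total_n, f_sym_n, phi, amp = partition_nitrogen(s, cfg)
    f_total_c, psi = partition_carbon(s, cfg)
    g_host = growth_rate(
        ratio_to_atom_fraction(s.host[0].ratio_c),
        cfg.a_nat_c,
        cfg.a_source_c,
        cfg.t_days,
    )
    g_syms = [
        growth_rate(
            ratio_to_atom_fraction(m.ratio_c), cfg.a_nat_c, cfg.a_source_c, cfg.t_days
        )
        for m, _ in s.symbionts
    ]
    return PartitionResult(
        symbiosis_id=s.symbiosis_id,
        f_total_n=f_total_n,
        f_sym_n=f_sym_n,
        transfer_fraction_n=phi,
        amplification_n=amp,
        f_total_c=f_total_c,
        carbon_transfer_fraction=psi,
        growth_host=g_host,
        growth_sym_mean=sum(g_syms) / len(g_syms),
        growth_symbiosis=symbiosis_growth(s, cfg),
    )
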