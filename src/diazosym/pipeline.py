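"""Table schemas, config loading and the analysis stages.

Everything on disk is TSV (data) or TOML (configuration).  Stages are
plain functions DataFrame -> DataFrame so they compose in memory; the
CLI in :mod:`diazosym.cli` wires them to files and writes a run
manifest.  Stage order: simulate -> cellrates -> partition -> scale,
with bulkrate and detect as independent branches.
"""

from __future__ import annotations

import hashlib
import json
import math
import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bulk import BulkEndpoint, bulk_fixation_rate, replicate_summary
from .census import abundance_from_count, contribution_percent, volumetric_rate
from .detect import (
    CoverageRecord,
    breadth_from_depth,
    detect_presence,
    expected_breadth,
    qpcr_transform,
)
from .errors import SaturationError, ValidationError
from .isotopes import (
    BiomassParams,
    Compartment,
    IsotopeMeasurement,
    LabelingConfig,
    biomass_from_volume,
    biovolume,
    fixation_rate,
    growth_rate,
    ratio_to_atom_fraction,
)
from .mass_balance import SymbiosisRecord, partition
from .simulate import ROI_COLUMNS, SimConfig

__all__ = [
    "load_config",
    "load_roi_table",
    "cell_rates",
    "build_symbioses",
    "partition_table",
    "scale_table",
    "bulk_rate_table",
    "detect_table",
    "qpcr_table",
    "depth_to_coverage_table",
    "write_manifest",
]

BULK_COLUMNS = [
    "station",
    "element",
    "replicate_id",
    "a_pn_t0",
    "a_pn_t",
    "pn_conc_umol_l",
    "t_days",
]
CENSUS_COLUMNS = ["taxon", "count", "volume_l"]
COVERAGE_COLUMNS = ["sample_id", "genome_id", "mean_coverage", "observed_breadth"]
DEPTH_COLUMNS = ["contig", "position", "depth"]
QPCR_COLUMNS = ["sample_id", "lat", "lon", "nifh_copies"]


# ---------------------------------------------------------------- config


def load_config(path: str | Path) -> dict:
    """Parse a TOML config into typed sections.

    Recognised sections: ``[labeling]``, ``[biomass]``, ``[simulate]``,
    ``[census]`` (``bulk_rate_nmol_l_d``), ``[detect]`` (``theta``).
    Missing sections fall back to documented defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    labeling = LabelingConfig(**raw.get("labeling", {}))
    biomass = BiomassParams(**raw.get("biomass", {}))
    sim_kwargs = dict(raw.get("simulate", {}))
    sim = SimConfig(**sim_kwargs, labeling=labeling, biomass=biomass)
    return {
        "labeling": labeling,
        "biomass": biomass,
        "simulate": sim,
        "census": raw.get("census", {}),
        "detect": raw.get("detect", {}),
        "raw": raw,
    }


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{what}: missing column(s) {', '.join(repr(c) for c in missing)}"
        )


def _read_tsv(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"symbiosis_id": str, "roi_id": str})
    _require_columns(df, required, what)
    return df


# ------------------------------------------------------------- ROI input


def load_roi_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a ROI measurement TSV (schema of ROI_COLUMNS)."""
    df = _read_tsv(path, ROI_COLUMNS, "ROI table")
    for idx, row in df.iterrows():
        comp = row["compartment"]
        if comp not in ("host", "symbiont"):
            raise ValidationError(
                f"ROI table row {idx}: compartment must be 'host' or "
                f"'symbiont', got {comp!r}"
            )
        for col in ("ratio_c", "ratio_n"):
            v = row[col]
            if pd.isna(v) or v < 0:
                raise ValidationError(
                    f"ROI table row {idx} ({row['roi_id']}): column {col!r} "
                    f"must be a non-negative number, got {v!r}"
                )
    return df


def _row_to_measurement(row: pd.Series) -> IsotopeMeasurement:
    def opt(col: str) -> float | None:
        v = row.get(col)
        if v is None or (isinstance(v, str) and not v.strip()):
            return None
        f = float(v)
        return None if math.isnan(f) else f

    return IsotopeMeasurement(
        roi_id=str(row["roi_id"]),
        symbiosis_id=str(row["symbiosis_id"]),
        compartment=Compartment(row["compartment"]),
        ratio_c=float(row["ratio_c"]),
        ratio_n=float(row["ratio_n"]),
        counts_c_total=opt("counts_c_total"),
        counts_n_total=opt("counts_n_total"),
        length_um=opt("length_um"),
        width_um=opt("width_um"),
        diameter_um=opt("diameter_um"),
    )


# ----------------------------------------------------------- cell rates


def cell_rates(
    roi: pd.DataFrame,
    labeling: LabelingConfig,
    biomass: BiomassParams | None = None,
) -> pd.DataFrame:
    """Per-cell biomass, atom fractions, fixation rates and growth.

    One output row per ROI.  Cells whose carbon enrichment sits at or
    above the label source (saturation) get ``growth = NaN``.
    """
    biomass = biomass or BiomassParams()
    rows = []
    for _, r in roi.iterrows():
        m = _row_to_measurement(r)
        v = biovolume(m)
        b = biomass_from_volume(v, m.compartment, biomass)
        a_c = ratio_to_atom_fraction(m.ratio_c)
        a_n = ratio_to_atom_fraction(m.ratio_n)
        fix_c = fixation_rate(
            a_c, labeling.a_nat_c, labeling.a_source_c, b.c_content_fmol,
            labeling.t_days,
        )
        fix_n = fixation_rate(
            a_n, labeling.a_nat_n, labeling.a_source_n, b.n_content_fmol,
            labeling.t_days,
        )
        try:
            g = growth_rate(
                a_c, labeling.a_nat_c, labeling.a_source_c, labeling.t_days
            )
        except SaturationError:
            g = math.nan
        rows.append(
            {
                "roi_id": m.roi_id,
                "symbiosis_id": m.symbiosis_id,
                "compartment": m.compartment.value,
                "biovolume_um3": v,
                "c_content_fmol": b.c_content_fmol,
                "n_content_fmol": b.n_content_fmol,
                "atom_fraction_c": a_c,
                "atom_fraction_n": a_n,
                "fix_c_fmol_d": fix_c,
                "fix_n_fmol_d": fix_n,
                "growth_div_d": g,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ partition


def build_symbioses(
    roi: pd.DataFrame, biomass: BiomassParams | None = None
) -> list[SymbiosisRecord]:
    """Group a ROI table into SymbiosisRecords (one host + its symbionts)."""
    biomass = biomass or BiomassParams()
    records = []
    for sid, grp in roi.groupby("symbiosis_id", sort=True):
        host = None
        syms = []
        for _, r in grp.iterrows():
            m = _row_to_measurement(r)
            b = biomass_from_volume(biovolume(m), m.compartment, biomass)
            if m.compartment is Compartment.HOST:
                if host is not None:
                    raise ValidationError(
                        f"symbiosis {sid}: more than one host ROI"
                    )
                host = (m, b)
            else:
                syms.append((m, b))
        if host is None:
            raise ValidationError(f"symbiosis {sid}: no host ROI")
        records.append(
            SymbiosisRecord(symbiosis_id=str(sid), host=host, symbionts=tuple(syms))
        )
    return records


def partition_table(
    roi: pd.DataFrame,
    labeling: LabelingConfig,
    biomass: BiomassParams | None = None,
) -> pd.DataFrame:
    """One row of partition statistics per symbiosis."""
    rows = [
        asdict(partition(s, labeling)) for s in build_symbioses(roi, biomass)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- scale


def scale_table(
    census: pd.DataFrame,
    per_symbiosis_rate_fmol_d: float,
    bulk_rate_nmol_l_d: float | None = None,
) -> pd.DataFrame:
    """Census counts -> abundances -> volumetric rates and contributions.

    The scaling quantity is the mean whole-symbiosis N2-fixation rate
    (host-recovered plus symbiont-retained nitrogen).
    """
    _require_columns(census, CENSUS_COLUMNS, "census table")
    rows = []
    for idx, r in census.iterrows():
        try:
            rec = abundance_from_count(
                int(r["count"]), float(r["volume_l"]), taxon=str(r["taxon"])
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"census table row {idx}: {exc}") from exc
        vr = volumetric_rate(per_symbiosis_rate_fmol_d, rec.abundance_per_l)
        contrib = (
            contribution_percent(vr, bulk_rate_nmol_l_d)
            if bulk_rate_nmol_l_d and bulk_rate_nmol_l_d > 0
            else math.nan
        )
        rows.append(
            {
                **asdict(rec),
                "rate_nmol_per_l_d": vr,
                "contribution_percent": contrib,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- bulkrate


def bulk_rate_table(
    bulk: pd.DataFrame, labeling: LabelingConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bottle rates and per-(station, element) replicate summaries.

    The label source atom fraction is taken from the config per element
    (N -> a_source_n, C -> a_source_c).
    """
    _require_columns(bulk, BULK_COLUMNS, "bulk table")
    per_bottle = []
    for idx, r in bulk.iterrows():
        el = str(r["element"]).upper()
        if el not in ("N", "C"):
            raise ValidationError(
                f"bulk table row {idx}: element must be 'N' or 'C', got "
                f"{r['element']!r}"
            )
        a_source = labeling.a_source_n if el == "N" else labeling.a_source_c
        e = BulkEndpoint(
            a_pn_t0=float(r["a_pn_t0"]),
            a_pn_t=float(r["a_pn_t"]),
            pn_conc=float(r["pn_conc_umol_l"]),
            t_days=float(r["t_days"]),
            replicate_id=str(r["replicate_id"]),
        )
        per_bottle.append(
            {
                "station": r["station"],
                "element": el,
                "replicate_id": e.replicate_id,
                "rate_nmol_l_d": bulk_fixation_rate(e, a_source),
            }
        )
    per_bottle_df = pd.DataFrame(per_bottle)
    summaries = []
    for (station, el), grp in per_bottle_df.groupby(["station", "element"]):
        mean, sd, n = replicate_summary(list(grp["rate_nmol_l_d"]))
        summaries.append(
            {
                "station": station,
                "element": el,
                "mean_nmol_l_d": mean,
                "sd_nmol_l_d": sd,
                "n": n,
            }
        )
    return per_bottle_df, pd.DataFrame(summaries)


# --------------------------------------------------------------- detect


def depth_to_coverage_table(depth: pd.DataFrame, sample_id: str, genome_id: str) -> pd.DataFrame:
    """Collapse a per-position depth TSV into one coverage/breadth row."""
    _require_columns(depth, DEPTH_COLUMNS, "depth table")
    cov, breadth = breadth_from_depth(depth["depth"].to_numpy())
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "genome_id": genome_id,
                "mean_coverage": cov,
                "observed_breadth": breadth,
            }
        ]
    )


def detect_table(coverage: pd.DataFrame, theta: float = 0.95) -> pd.DataFrame:
    """Presence calls from a per-sample coverage/breadth summary."""
    _require_columns(coverage, COVERAGE_COLUMNS, "coverage table")
    out = coverage.copy()
    expected = []
    present = []
    for idx, r in coverage.iterrows():
        try:
            rec = CoverageRecord(
                sample_id=str(r["sample_id"]),
                genome_id=str(r["genome_id"]),
                mean_coverage=float(r["mean_coverage"]),
                observed_breadth=float(r["observed_breadth"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"coverage table row {idx}: {exc}") from exc
        expected.append(expected_breadth(rec.mean_coverage))
        present.append(detect_presence(rec, theta))
    out["expected_breadth"] = expected
    out["present"] = present
    return out


def qpcr_table(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Log-transformed qPCR table ready for mapping (zeros flagged)."""
    _require_columns(qpcr, ["sample_id", "nifh_copies"], "qPCR table")
    recs = qpcr_transform(
        qpcr["nifh_copies"].tolist(), qpcr["sample_id"].astype(str).tolist()
    )
    out = qpcr.copy()
    out["log10_copies"] = [r.log_value if r.log_value is not None else math.nan for r in recs]
    out["filtered"] = [r.filtered for r in recs]
    return out


# ------------------------------------------------------------- manifest


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: Path,
    *,
    stages: list[str],
    seed: int | None,
    config_snapshot: dict,
    inputs: list[Path],
    outputs: list[Path],
) -> Path:
    """Write a run manifest tracing outputs to config + inputs + seed."""
    manifest = {
        "tool": "diazosym",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": config_snapshot,
        "inputs": {str(p): _digest(p) for p in inputs if p.exists()},
        "outputs": {str(p): _digest(p) for p in outputs if p.exists()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
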