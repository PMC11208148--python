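"""Genome presence detection from coverage/breadth, and qPCR transforms.

A genome is called present in a metagenome when the observed breadth of
coverage (fraction of positions covered by >= 1 read) is close to the
breadth expected for its mean coverage under random read placement,

    expected breadth = 1 - exp(-0.883 * coverage),

which guards against spurious "coverage" piled onto a few conserved
regions.  "Close to" is operationalised as a configurable ratio
threshold theta (default 0.95).  qPCR gene counts are prepared for
mapping with a +1 pseudocount and log10 transform, dropping zero-count
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "BREADTH_DECAY",
    "CoverageRecord",
    "QpcrRecord",
    "expected_breadth",
    "detect_presence",
    "breadth_from_depth",
    "qpcr_transform",
]

#: Empirical decay constant relating mean coverage to expected breadth.
BREADTH_DECAY = 0.883


@dataclass(frozen=True)
class CoverageRecord:
    sample_id: str
    genome_id: str
    mean_coverage: float
    observed_breadth: float

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise DomainError(f"mean_coverage must be >= 0, got {self.mean_coverage}")
        if not 0.0 <= self.observed_breadth <= 1.0:
            raise DomainError(
                f"observed_breadth must be in [0, 1], got {self.observed_breadth}"
            )


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    nifh_copies: float
    log_value: float | None  # log10(copies + 1); None when filtered out
    filtered: bool


def expected_breadth(coverage: float) -> float:
    """Breadth expected at a given mean coverage under random placement."""
    if coverage < 0:
        raise DomainError(f"coverage must be >= 0, got {coverage}")
    return 1.0 - math.exp(-BREADTH_DECAY * coverage)


def detect_presence(rec: CoverageRecord, theta: float = 0.95) -> bool:
    """True when the genome's observed breadth reaches a fraction theta of
    the breadth expected for its mean coverage (and coverage is non-zero)."""
    if not 0.0 < theta <= 1.0:
        raise DomainError(f"theta must be in (0, 1], got {theta}")
    if rec.mean_coverage <= 0:
        return False
    return rec.observed_breadth >= theta * expected_breadth(rec.mean_coverage)


def breadth_from_depth(depth_profile: Sequence[float]) -> tuple[float, float]:
    """(mean coverage, observed breadth) from a per-position depth vector."""
    depths = np.asarray(depth_profile, dtype=float)
    if depths.size == 0:
        raise DomainError("depth profile is empty")
    if (depths < 0).any():
        raise DomainError("depths must be >= 0")
    return float(depths.mean()), float((depths >= 1).mean())


def qpcr_transform(
    counts: Sequence[float], sample_ids: Sequence[str] | None = None
) -> list[QpcrRecord]:
    """Pseudocount-1 log10 transform of gene copy numbers.

    Zero-count samples are flagged ``filtered`` (log_value None) and are
    meant to be plotted/mapped separately; the choice of filtering before
    or after the transform is immaterial since log10(0 + 1) = 0.
    """
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(counts))]
    if len(ids) != len(counts):
        raise DomainError("sample_ids and counts must have equal length")
    out: list[QpcrRecord] = []
    for sid, c in zip(ids, counts):
        if c < 0:
            raise DomainError(f"sample {sid}: negative copy number {c}")
        if c == 0:
            out.append(QpcrRecord(sid, 0.0, None, True))
        else:
            out.append(QpcrRecord(sid, float(c), math.log10(c + 1.0), False))
    return out
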