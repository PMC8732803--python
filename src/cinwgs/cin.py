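"""Arm-level Z-scores, the CIN score with high/low classification, and the
TP53 copy-loss call.

The arm Z standardizes a tumor's arm-aggregate scaled coverage against the
control panel's arm-level mean/sd:

    z_arm = (cov_arm_tumor - mean(cov_arm_controls)) / sd(cov_arm_controls)

The CIN score sums, over arms, arm length (Mb) times |z|; a score above the
cutoff (default 4000) is classified High. The locus-level Z for TP53 follows
the same construction, with loss called at z <= -3 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import ControlPanel, CoverageProfile, _aggregate, scale_to_unit_mean
from .genome import BinGrid, ChromosomeArm, Locus
from .segmentation import SegmentSet

DEFAULT_CIN_CUTOFF = 4000.0
DEFAULT_TP53_THRESHOLD = -3.0

CIN_CONVENTIONS = ("abs_arm", "signed_arm", "abs_segment")


@dataclass
class ArmZ:
    arm: ChromosomeArm
    coverage_tumor: float
    z: float

    @property
    def length_mb(self) -> float:
        return self.arm.length_mb


@dataclass
class CINResult:
    sample_id: str
    arm_z: list[ArmZ]
    cin_score: float
    cutoff: float
    category: str  # "High" | "Low"
    excluded_arms: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm": [a.arm.name for a in self.arm_z],
                "chrom": [a.arm.chrom for a in self.arm_z],
                "length_mb": [a.length_mb for a in self.arm_z],
                "coverage_tumor": [a.coverage_tumor for a in self.arm_z],
                "z": [a.z for a in self.arm_z],
            }
        )


@dataclass
class TP53Call:
    sample_id: str
    z_tp53: float
    loss: bool
    threshold: float = DEFAULT_TP53_THRESHOLD


def arm_zscores(
    tumor: CoverageProfile, panel: ControlPanel, grid: BinGrid
) -> tuple[list[ArmZ], list[str]]:
    """Per-arm Z-scores for a (raw, library-scaled) tumor profile.

    Arms whose panel sd is unusable (NaN or below floor) are excluded and
    returned separately.
    """
    tumor = scale_to_unit_mean(tumor)
    out: list[ArmZ] = []
    excluded: list[str] = []
    for arm in grid.arms:
        mu = panel.arm_mean.get(arm.name, float("nan"))
        sd = panel.arm_sd.get(arm.name, float("nan"))
        idx = panel.arm_usable(arm.name)
        cov = _aggregate(tumor.values, idx)
        if not np.isfinite(mu) or not np.isfinite(sd) or sd <= 0 or not np.isfinite(cov):
            excluded.append(arm.name)
            continue
        out.append(ArmZ(arm=arm, coverage_tumor=cov, z=(cov - mu) / sd))
    return out, excluded


def cin_score(arm_z: list[ArmZ], signed: bool = False) -> float:
    """CIN = sum over arms of length_mb * |z| (signed sum behind a flag)."""
    if not arm_z:
        raise ValueError("empty arm list")
    if signed:
        return float(sum(a.length_mb * a.z for a in arm_z))
    return float(sum(a.length_mb * abs(a.z) for a in arm_z))


def segment_cin_score(segments: SegmentSet) -> float:
    """Alternative scorer: sum over CBS segments of length_mb * |mean_z|."""
    return float(
        sum((s.end_bp - s.start_bp) / 1e6 * abs(s.mean_z) for s in segments.segments)
    )


def classify_cin(score: float, cutoff: float = DEFAULT_CIN_CUTOFF) -> str:
    """High iff score strictly exceeds the cutoff (4000 itself is Low)."""
    return "High" if score > cutoff else "Low"


def evaluate_cin(
    sample_id: str,
    arm_z: list[ArmZ],
    excluded_arms: list[str],
    cutoff: float = DEFAULT_CIN_CUTOFF,
    signed: bool = False,
) -> CINResult:
    score = cin_score(arm_z, signed=signed)
    return CINResult(
        sample_id=sample_id,
        arm_z=arm_z,
        cin_score=score,
        cutoff=cutoff,
        category=classify_cin(abs(score), cutoff),
        excluded_arms=excluded_arms,
    )


def call_tp53(
    tumor: CoverageProfile,
    panel: ControlPanel,
    locus: Locus,
    threshold: float = DEFAULT_TP53_THRESHOLD,
) -> TP53Call:
    """Locus-aggregate Z against the panel; loss iff z <= threshold."""
    tumor = scale_to_unit_mean(tumor)
    mu = panel.locus_mean.get(locus.name, float("nan"))
    sd = panel.locus_sd.get(locus.name, float("nan"))
    if not np.isfinite(mu) or not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"panel has no usable aggregate for locus {locus.name!r}")
    idx = panel.grid.locus_bins(locus)
    idx = idx[panel.usable[idx]]
    if len(idx) == 0:
        raise ValueError(f"locus {locus.name!r} has no usable member bins")
    cov = _aggregate(tumor.values, idx)
    z = (cov - mu) / sd
    return TP53Call(
        sample_id=tumor.sample_id, z_tp53=float(z), loss=bool(z <= threshold),
        threshold=threshold,
    )
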