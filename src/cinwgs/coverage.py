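"""Binned coverage profiles, the control panel, and Z-normalization.

The normalization contract: every profile is first scaled so its mean depth
over usable bins equals 1 (library-size normalization), then each tumor bin
is standardized against the per-bin mean and sample standard deviation of the
scaled control panel:

    z = (cov_tumor - mean(cov_controls)) / sd(cov_controls)

Arm-level and locus-level aggregates (mean scaled coverage over usable bins)
are standardized the same way against the panel's matching aggregates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import BinGrid, Locus, LookupError_

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-6  # panel bins with sd below this (post-scaling) are unusable
DEFAULT_MIN_READ_PAIRS = 10_000_000


class CoverageError(ValueError):
    pass


class PanelError(ValueError):
    pass


@dataclass
class CoverageProfile:
    """Per-bin coverage values for one sample on a fixed grid.

    ``values`` has one entry per grid bin; bins with no data and excluded
    bins are NaN, never 0. ``kind`` is "raw" (mean depth per bin, possibly
    library-scaled) or "normalized" (panel Z per bin).
    """

    sample_id: str
    grid: BinGrid
    values: np.ndarray
    kind: str = "raw"
    total_read_pairs: int | None = None
    scaled: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_bins:
            raise CoverageError(
                f"profile length {len(self.values)} != grid bins {self.grid.n_bins}"
            )
        if self.kind not in ("raw", "normalized"):
            raise CoverageError(f"bad profile kind {self.kind!r}")

    @property
    def usable(self) -> np.ndarray:
        return self.grid.usable & np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        g = self.grid
        return pd.DataFrame(
            {
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "arm": g.arm_name,
                "value": self.values,
            }
        )


@dataclass
class ControlPanel:
    """Per-bin / per-arm / per-locus mean and sd across scaled controls."""

    grid: BinGrid
    n_controls: int
    bin_mean: np.ndarray
    bin_sd: np.ndarray
    usable: np.ndarray
    arm_mean: dict[str, float]
    arm_sd: dict[str, float]
    locus_mean: dict[str, float]
    locus_sd: dict[str, float]
    loci: dict[str, Locus] = field(default_factory=dict)

    def arm_usable(self, arm_name: str) -> np.ndarray:
        idx = self.grid.bins_of_arm(arm_name)
        return idx[self.usable[idx]]


def scale_to_unit_mean(profile: CoverageProfile) -> CoverageProfile:
    """Library-size normalization: mean over usable bins becomes 1."""
    if profile.scaled:
        return profile
    usable = profile.usable
    if not usable.any():
        raise CoverageError(f"profile {profile.sample_id}: no usable bins")
    m = float(np.nanmean(profile.values[usable]))
    if m <= 0:
        raise CoverageError(f"profile {profile.sample_id}: non-positive mean depth")
    return replace(profile, values=profile.values / m, scaled=True)


def bin_depth(
    depth_records: Iterable[tuple],
    grid: BinGrid,
    sample_id: str = "sample",
    total_read_pairs: int | None = None,
) -> CoverageProfile:
    """Accumulate depth records into mean per-base depth per grid bin.

    Accepts per-base records ``(chrom, pos, depth)`` or interval records
    ``(chrom, start, end, count)``; the two shapes may not be mixed. Interval
    counts are spread uniformly over the interval, so a bin's value is always
    total depth-units landing in the bin divided by the bin width. Bins that
    receive no data stay NaN. Records on contigs absent from the grid are
    skipped with a warning.
    """
    total = np.zeros(grid.n_bins, dtype=float)
    touched = np.zeros(grid.n_bins, dtype=bool)
    n_records = 0
    n_skipped = 0
    for rec in depth_records:
        n_records += 1
        if len(rec) == 3:
            chrom, pos, depth = rec
            try:
                i = grid.locate(chrom, int(pos))
            except LookupError_:
                n_skipped += 1
                continue
            if i is None:
                continue
            total[i] += float(depth)
            touched[i] = True
        elif len(rec) == 4:
            chrom, start, end, count = rec
            start, end = int(start), int(end)
            if end <= start:
                raise CoverageError(f"bad interval {chrom}:{start}-{end}")
            per_base = float(count) / (end - start)
            pos = start
            while pos < end:
                try:
                    i = grid.locate(chrom, pos)
                except LookupError_:
                    n_skipped += 1
                    break
                if i is None:
                    # uncovered gap: jump to the next bin start on this contig
                    sl = grid._chrom_slices[chrom]
                    nxt = grid.start[sl][np.searchsorted(grid.start[sl], pos, "right"):]
                    if len(nxt) == 0:
                        break
                    pos = int(nxt[0])
                    continue
                stop = min(end, int(grid.end[i]))
                total[i] += per_base * (stop - pos)
                touched[i] = True
                pos = stop
        else:
            raise CoverageError(f"record of width {len(rec)} not understood")
    if n_records == 0:
        raise CoverageError("empty depth input")
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} record(s) on contigs absent from grid")
    width = (grid.end - grid.start).astype(float)
    values = np.where(touched, total / width, np.nan)
    values[grid.excluded] = np.nan
    return CoverageProfile(
        sample_id=sample_id,
        grid=grid,
        values=values,
        kind="raw",
        total_read_pairs=total_read_pairs,
    )


def read_depth_tsv(path, grid: BinGrid, sample_id: str | None = None) -> CoverageProfile:
    """Read a per-base depth TSV (chrom, pos, depth) or BED4 interval file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    sid = sample_id or str(path)
    if df.shape[1] == 3:
        recs = df.itertuples(index=False, name=None)
    elif df.shape[1] >= 4:
        recs = df.iloc[:, :4].itertuples(index=False, name=None)
    else:
        raise CoverageError(f"{path}: expected 3 or 4 columns, got {df.shape[1]}")
    return bin_depth(recs, grid, sample_id=sid)


def _aggregate(values: np.ndarray, idx: np.ndarray) -> float:
    """Mean scaled coverage over a set of bins (NaN if none usable)."""
    if len(idx) == 0:
        return float("nan")
    v = values[idx]
    v = v[np.isfinite(v)]
    return float(np.mean(v)) if len(v) else float("nan")


def build_panel(
    controls: Sequence[CoverageProfile],
    grid: BinGrid,
    loci: Sequence[Locus] = (),
) -> ControlPanel:
    """Per-bin, per-arm and per-locus mean/sd across library-scaled controls.

    Standard deviations use the n-1 denominator. Bins that are usable in
    fewer than two controls or whose sd falls below ``SD_FLOOR`` are flagged
    unusable.
    """
    if len(controls) < 2:
        raise PanelError("need at least 2 controls")
    for c in controls:
        if c.grid is not grid and c.grid.n_bins != grid.n_bins:
            raise PanelError(f"control {c.sample_id}: grid mismatch")
        if not np.isfinite(c.values).any():
            raise PanelError(f"control {c.sample_id} is all-missing")
    scaled = [scale_to_unit_mean(c) for c in controls]
    mat = np.vstack([c.values for c in scaled])  # (n_controls, n_bins)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_ok = np.isfinite(mat).sum(axis=0)
        bin_mean = np.nanmean(mat, axis=0)
        bin_sd = np.nanstd(mat, axis=0, ddof=1)
    usable = grid.usable & (n_ok >= 2) & np.isfinite(bin_sd) & (bin_sd >= SD_FLOOR)

    arm_mean: dict[str, float] = {}
    arm_sd: dict[str, float] = {}
    for arm in grid.arms:
        idx = grid.bins_of_arm(arm.name)
        idx = idx[usable[idx]]
        aggs = np.array([_aggregate(row, idx) for row in mat])
        if len(idx) == 0 or not np.isfinite(aggs).all():
            arm_mean[arm.name] = float("nan")
            arm_sd[arm.name] = float("nan")
        else:
            arm_mean[arm.name] = float(np.mean(aggs))
            arm_sd[arm.name] = float(np.std(aggs, ddof=1))

    locus_mean: dict[str, float] = {}
    locus_sd: dict[str, float] = {}
    loci_map: dict[str, Locus] = {}
    for locus in loci:
        loci_map[locus.name] = locus
        idx = grid.locus_bins(locus)
        idx = idx[usable[idx]]
        aggs = np.array([_aggregate(row, idx) for row in mat])
        if len(idx) == 0 or not np.isfinite(aggs).all():
            locus_mean[locus.name] = float("nan")
            locus_sd[locus.name] = float("nan")
        else:
            locus_mean[locus.name] = float(np.mean(aggs))
            locus_sd[locus.name] = float(np.std(aggs, ddof=1))

    return ControlPanel(
        grid=grid,
        n_controls=len(controls),
        bin_mean=bin_mean,
        bin_sd=bin_sd,
        usable=usable,
        arm_mean=arm_mean,
        arm_sd=arm_sd,
        locus_mean=locus_mean,
        locus_sd=locus_sd,
        loci=loci_map,
    )


def normalize(
    tumor: CoverageProfile,
    panel: ControlPanel,
    max_unusable_fraction: float = 0.5,
) -> CoverageProfile:
    """Per-bin panel Z-scores for a (library-scaled) tumor profile."""
    tumor = scale_to_unit_mean(tumor)
    ok = panel.usable & np.isfinite(tumor.values)
    frac_unusable = 1.0 - ok.sum() / max(1, panel.grid.usable.sum())
    if frac_unusable > max_unusable_fraction:
        raise CoverageError(
            f"{tumor.sample_id}: {frac_unusable:.1%} of usable grid bins "
            "cannot be normalized"
        )
    z = np.full(panel.grid.n_bins, np.nan)
    z[ok] = (tumor.values[ok] - panel.bin_mean[ok]) / panel.bin_sd[ok]
    return CoverageProfile(
        sample_id=tumor.sample_id,
        grid=panel.grid,
        values=z,
        kind="normalized",
        total_read_pairs=tumor.total_read_pairs,
        scaled=True,
        meta=dict(tumor.meta, n_controls=panel.n_controls),
    )


def check_depth(
    profile: CoverageProfile, min_read_pairs: int = DEFAULT_MIN_READ_PAIRS
) -> dict:
    """Depth QC annotation. Never blocks the pipeline."""
    n = profile.total_read_pairs
    if n is None:
        return {
            "sample_id": profile.sample_id,
            "total_read_pairs": None,
            "status": "unknown",
            "passed": True,
            "warning": "read-pair count unavailable",
        }
    passed = n >= min_read_pairs
    return {
        "sample_id": profile.sample_id,
        "total_read_pairs": int(n),
        "status": "pass" if passed else "fail",
        "passed": bool(passed),
        "warning": None,
    }


def write_profile_tsv(profile: CoverageProfile, path) -> None:
    """Normalized profile as TSV (chrom, start, end, arm, z)."""
    df = profile.to_frame()
    col = "z" if profile.kind == "normalized" else "depth"
    df = df.rename(columns={"value": col})
    df.to_csv(path, sep="\t", index=False)


def read_profile_tsv(path, grid: BinGrid, sample_id: str | None = None) -> CoverageProfile:
    """Read back a profile written by :func:`write_profile_tsv`."""
    df = pd.read_csv(path, sep="\t")
    value_col = next((c for c in ("z", "depth", "value") if c in df.columns), None)
    if value_col is None:
        raise CoverageError(f"{path}: no value column (z/depth/value)")
    values = np.full(grid.n_bins, np.nan)
    pos_to_idx = {
        (c, s): i for i, (c, s) in enumerate(zip(grid.chrom, grid.start))
    }
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.start))
        if key not in pos_to_idx:
            raise CoverageError(f"{path}: bin {key} not on grid")
        values[pos_to_idx[key]] = getattr(row, value_col)
    kind = "normalized" if value_col == "z" else "raw"
    return CoverageProfile(
        sample_id=sample_id or str(path),
        grid=grid,
        values=values,
        kind=kind,
        scaled=kind == "normalized",
    )


def write_bedgraph(profile: CoverageProfile, path) -> None:
    df = profile.to_frame().dropna(subset=["value"])
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{profile.sample_id}"\n')
        df[["chrom", "start", "end", "value"]].to_csv(
            fh, sep="\t", index=False, header=False
        )
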