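"""Synthetic LPWGS inputs with known ground truth.

Bin counts are negative-binomial (Poisson when ``dispersion == 0``) around
bin-specific baseline rates shared by every sample drawn from the same seed;
the shared lognormal baseline heterogeneity is exactly the structure that
panel normalization removes. Tumors multiply the baseline by
``purity * copy_ratio + (1 - purity)`` inside each injected CNA segment.

All generators are pure functions of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .genome import BinGrid, ChromosomeArm, Locus, build_bin_grid

TOY_BIN_SIZE = 1_000_000

#: TP53 stand-in on the toy genome (inside arm 3p).
TOY_TP53 = Locus("TP53", "chr3", 10_200_000, 10_220_000)


def toy_genome(bin_size: int = TOY_BIN_SIZE) -> BinGrid:
    """Small 3-chromosome / 6-arm grid (~290 bins) for fast tests."""
    arms = []
    for i in (1, 2, 3):
        chrom = f"chr{i}"
        arms.append(ChromosomeArm(f"{i}p", chrom, 0, 48_000_000))
        arms.append(ChromosomeArm(f"{i}q", chrom, 52_000_000, 100_000_000))
    return build_bin_grid(arms, bin_size)


@dataclass(frozen=True)
class CNASpec:
    """Ground-truth copy-number aberration over arm-local bin offsets."""

    arm: str
    start_bin: int  # offsets within the arm, half-open
    end_bin: int
    copy_ratio: float  # 0.5 = one-copy loss, 1.5 = one-copy gain

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be positive")
        if not self.start_bin < self.end_bin:
            raise ValueError("empty CNA bin range")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_controls: int = 20
    mean_depth: float = 1000.0  # expected count per bin
    dispersion: float = 0.05  # NB overdispersion; 0 -> Poisson
    baseline_sigma: float = 0.1  # lognormal sd of shared per-bin rates
    purity: float = 1.0
    cna_list: tuple[CNASpec, ...] = ()
    tp53_deleted: bool = False
    tp53_copy_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("n_controls must be >= 2")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if self.mean_depth <= 0 or self.dispersion < 0 or self.baseline_sigma < 0:
            raise ValueError("rates must be positive")


@dataclass
class TumorTruth:
    """Everything needed to compute expected downstream quantities."""

    config: SimConfig
    bin_factor: np.ndarray  # per-bin expected rate multiplier
    baseline_rate: np.ndarray
    expected_arm_z: dict[str, float]
    expected_arm_factor: dict[str, float]


def baseline_rates(config: SimConfig, grid: BinGrid) -> np.ndarray:
    """Shared per-bin expected counts, fixed by the seed."""
    rng = np.random.default_rng([config.seed, 0])
    mult = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=grid.n_bins)
    return config.mean_depth * mult


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float):
    if dispersion == 0:
        return rng.poisson(mu).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def _as_profile(grid: BinGrid, counts: np.ndarray, sample_id: str) -> CoverageProfile:
    values = counts.astype(float)
    values[grid.excluded] = np.nan
    total_pairs = int(np.nansum(values))
    return CoverageProfile(
        sample_id=sample_id, grid=grid, values=values, kind="raw",
        total_read_pairs=total_pairs,
    )


def simulate_controls(config: SimConfig, grid: BinGrid) -> list[CoverageProfile]:
    rates = baseline_rates(config, grid)
    out = []
    for i in range(config.n_controls):
        rng = np.random.default_rng([config.seed, 1, i])
        counts = _draw_counts(rng, rates, config.dispersion)
        out.append(_as_profile(grid, counts, f"control-{i:03d}"))
    return out


def tumor_bin_factor(
    config: SimConfig, grid: BinGrid, locus: Locus = TOY_TP53
) -> np.ndarray:
    """Expected per-bin rate multiplier implied by the CNA list and purity."""
    factor = np.ones(grid.n_bins)
    for cna in config.cna_list:
        arm_bins = grid.bins_of_arm(cna.arm)
        if len(arm_bins) == 0:
            raise ValueError(f"CNA on unknown arm {cna.arm!r}")
        if cna.end_bin > len(arm_bins):
            raise ValueError(f"CNA bins exceed arm {cna.arm!r}")
        sel = arm_bins[cna.start_bin : cna.end_bin]
        factor[sel] *= config.purity * cna.copy_ratio + (1 - config.purity)
    if config.tp53_deleted:
        sel = grid.locus_bins(locus)
        factor[sel] *= config.purity * config.tp53_copy_ratio + (1 - config.purity)
    return factor


def _truth(config: SimConfig, grid: BinGrid, locus: Locus) -> TumorTruth:
    rates = baseline_rates(config, grid)
    factor = tumor_bin_factor(config, grid, locus)
    usable = grid.usable
    # expected library-scaled bin values
    ctrl_scale = float(np.mean(rates[usable]))
    tum_scale = float(np.mean((rates * factor)[usable]))
    exp_ctrl = rates / ctrl_scale
    exp_tum = rates * factor / tum_scale
    var_count = rates + config.dispersion * rates**2

    expected_arm_z: dict[str, float] = {}
    expected_arm_factor: dict[str, float] = {}
    for arm in grid.arms:
        idx = grid.bins_of_arm(arm.name)
        idx = idx[usable[idx]]
        if len(idx) == 0:
            continue
        agg_c = float(np.mean(exp_ctrl[idx]))
        agg_t = float(np.mean(exp_tum[idx]))
        sd_c = float(np.sqrt(np.sum(var_count[idx])) / (len(idx) * ctrl_scale))
        expected_arm_z[arm.name] = (agg_t - agg_c) / sd_c
        expected_arm_factor[arm.name] = float(np.mean(factor[idx]))
    return TumorTruth(
        config=config,
        bin_factor=factor,
        baseline_rate=rates,
        expected_arm_z=expected_arm_z,
        expected_arm_factor=expected_arm_factor,
    )


def simulate_tumor(
    config: SimConfig,
    grid: BinGrid,
    locus: Locus = TOY_TP53,
    sample_id: str = "tumor",
) -> tuple[CoverageProfile, TumorTruth]:
    truth = _truth(config, grid, locus)
    rng = np.random.default_rng([config.seed, 2])
    counts = _draw_counts(
        rng, truth.baseline_rate * truth.bin_factor, config.dispersion
    )
    return _as_profile(grid, counts, sample_id), truth


def simulate_cohort(
    n: int = 32,
    p_loss_given_high: float = 12 / 14,
    p_loss_given_low: float = 3 / 18,
    p_high: float = 14 / 32,
    hr_high: float = 6.5,
    censor_rate: float = 0.01,
    seed: int = 0,
    baseline_hazard: float = 0.02,
) -> pd.DataFrame:
    """Cohort table with CIN category, TP53 status and survival outcomes.

    Event times are exponential with the hazard multiplied by ``hr_high``
    for CIN-high cases; censoring is independent exponential with rate
    ``censor_rate``.
    """
    for p in (p_loss_given_high, p_loss_given_low, p_high):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if hr_high <= 0:
        raise ValueError("hr_high must be positive")
    rng = np.random.default_rng(seed)
    high = rng.random(n) < p_high
    p_loss = np.where(high, p_loss_given_high, p_loss_given_low)
    loss = rng.random(n) < p_loss
    hazard = baseline_hazard * np.where(high, hr_high, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame(
        {
            "sample_id": [f"sim-{i:04d}" for i in range(n)],
            "cin_category": np.where(high, "High", "Low"),
            "tp53_status": np.where(loss, "LOSS", "WT"),
            "time_months": np.maximum(time, 1e-9),
            "event": event,
        }
    )


def cohort_records(df: pd.DataFrame):
    """Cohort frame -> SurvivalRecord list (CIN high coded 1/0)."""
    from .stats import SurvivalRecord

    return [
        SurvivalRecord(
            sample_id=r.sample_id,
            time=float(r.time_months),
            event=bool(r.event),
            covariates={"cin_high": 1.0 if r.cin_category == "High" else 0.0},
        )
        for r in df.itertuples(index=False)
    ]


def euploid_config(seed: int, **kw) -> SimConfig:
    return SimConfig(seed=seed, **kw)


def with_cnas(config: SimConfig, cnas: list[CNASpec]) -> SimConfig:
    return replace(config, cna_list=tuple(cnas))
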