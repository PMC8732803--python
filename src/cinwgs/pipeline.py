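"""End-to-end per-sample pipeline: bin -> normalize -> segment -> arm Z ->
CIN score -> TP53 call -> report."""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from typing import Sequence

from . import cin as cin_mod
from .config import RunConfig
from .coverage import (
    ControlPanel,
    CoverageProfile,
    build_panel,
    check_depth,
    normalize,
    scale_to_unit_mean,
    write_profile_tsv,
)
from .genome import BinGrid, Locus, hg19_grid, tp53_locus
from .segmentation import segment_profile

logger = logging.getLogger(__name__)


def _version() -> str:
    try:
        return version("cinwgs")
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(
    tumor: CoverageProfile,
    controls: Sequence[CoverageProfile],
    config: RunConfig | None = None,
    grid: BinGrid | None = None,
    locus: Locus | None = None,
    panel: ControlPanel | None = None,
    outdir=None,
) -> dict:
    """Execute the full chain on binned profiles and return a JSON-able report.

    ``grid`` defaults to the packaged hg19 tiling at ``config.bin_size``;
    pass an explicit grid (and matching ``locus``) for other genomes.
    """
    config = config or RunConfig()
    if grid is None:
        grid = hg19_grid(config.bin_size, config.include_sex_chromosomes)
    if locus is None:
        locus = tp53_locus()
    logger.info(
        "pipeline start: sample=%s version=%s config=%s seed=%d",
        tumor.sample_id, _version(), config.digest(), config.seed,
    )

    stage = "qc"
    try:
        qc = check_depth(tumor, config.min_read_pairs)
        stage = "panel"
        if panel is None:
            panel = build_panel(controls, grid, loci=[locus])
        stage = "normalize"
        tumor_scaled = scale_to_unit_mean(tumor)
        normalized = normalize(tumor_scaled, panel)
        stage = "segment"
        segments = segment_profile(
            normalized,
            alpha=config.alpha,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        stage = "cin"
        arm_z, excluded_arms = cin_mod.arm_zscores(tumor_scaled, panel, grid)
        if config.cin_convention == "abs_segment":
            score = cin_mod.segment_cin_score(segments)
        else:
            score = cin_mod.cin_score(
                arm_z, signed=config.cin_convention == "signed_arm"
            )
        category = cin_mod.classify_cin(abs(score), config.cutoff)
        stage = "tp53"
        tp53 = cin_mod.call_tp53(tumor_scaled, panel, locus, config.tp53_threshold)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {
        "sample_id": tumor.sample_id,
        "version": _version(),
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "qc": qc,
        "cin_score": score,
        "cin_category": category,
        "cin_cutoff": config.cutoff,
        "arm_z": {a.arm.name: a.z for a in arm_z},
        "excluded_arms": excluded_arms,
        "z_tp53": tp53.z_tp53,
        "tp53_loss": tp53.loss,
        "tp53_threshold": config.tp53_threshold,
        "n_segments": len(segments.segments),
        "segments": json.loads(segments.to_json())["segments"],
    }

    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_profile_tsv(normalized, outdir / f"{tumor.sample_id}.normalized.tsv")
        segments.to_seg_frame().to_csv(
            outdir / f"{tumor.sample_id}.seg", sep="\t", index=False
        )
        cin_result = cin_mod.evaluate_cin(
            tumor.sample_id, arm_z, excluded_arms, config.cutoff
        )
        cin_result.to_frame().to_csv(
            outdir / f"{tumor.sample_id}.arm_z.tsv", sep="\t", index=False
        )
        with open(outdir / f"{tumor.sample_id}.report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
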