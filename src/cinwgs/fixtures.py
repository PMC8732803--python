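"""Packaged cohort tables and their fixture-level reproduction.

Two tables ship with the package: per-risk-group germline mutation counts
(five groups, 1151 screened cases) and the 32-case profiled cohort with
clinicopathologic fields, TP53 copy status and CIN category. The
``reproduce_cohort_stats`` report recomputes every headline rate and the
TP53-by-CIN Fisher test from raw counts and compares them with the expected
published values.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .stats import fisher_exact_2x2

EXPECTED = {
    "n_cases": 32,
    "n_cin_high": 14,
    "n_cin_low": 18,
    "n_tp53_loss": 15,
    "n_tp53_wt": 17,
    "loss_rate_high_pct": 85.71,
    "loss_rate_low_pct": 16.67,
    "fisher_p_2sf": 0.00021,
    "overall_mutation_rate_pct": 9.8,
    "familial_mutation_rate_pct": 16.5,
    "total_screened": 1151,
    "total_mutated": 113,
}


def _data_path(name: str):
    return importlib.resources.files("cinwgs.data") / name


def load_table1() -> pd.DataFrame:
    """Per-risk-group screening counts (group, n_cases, n_mutated)."""
    with importlib.resources.as_file(_data_path("table1_mutation_rates.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    if int(df["n_cases"].sum()) != EXPECTED["total_screened"]:
        raise ValueError("mutation-rate fixture fails its total-count invariant")
    if int(df["n_mutated"].sum()) != EXPECTED["total_mutated"]:
        raise ValueError("mutation-rate fixture fails its mutated-count invariant")
    return df


def load_cohort32() -> pd.DataFrame:
    """The 32-case profiled cohort with TP53 status and CIN category."""
    with importlib.resources.as_file(_data_path("cohort32.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    if len(df) != 32:
        raise ValueError(f"cohort fixture has {len(df)} rows, expected 32")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in cohort fixture")
    if not set(df["cin_category"]) <= {"High", "Low"}:
        raise ValueError("bad CIN category labels")
    if not set(df["tp53_status"]) <= {"LOSS", "WT"}:
        raise ValueError("bad TP53 status labels")
    return df


def tp53_cin_table(cohort: pd.DataFrame) -> np.ndarray:
    """2x2 table: rows TP53 (LOSS, WT), columns CIN (High, Low)."""
    a = ((cohort.tp53_status == "LOSS") & (cohort.cin_category == "High")).sum()
    b = ((cohort.tp53_status == "LOSS") & (cohort.cin_category == "Low")).sum()
    c = ((cohort.tp53_status == "WT") & (cohort.cin_category == "High")).sum()
    d = ((cohort.tp53_status == "WT") & (cohort.cin_category == "Low")).sum()
    return np.array([[a, b], [c, d]], dtype=np.int64)


def loss_rate_pct(cohort: pd.DataFrame, category: str) -> float:
    sub = cohort[cohort.cin_category == category]
    return round(100.0 * (sub.tp53_status == "LOSS").mean(), 2)


def mutation_rate_pct(table1: pd.DataFrame, group_match: str | None = None) -> float:
    if group_match is None:
        sub = table1
    else:
        sub = table1[table1.group.str.contains(group_match, case=False)]
        if len(sub) == 0:
            raise ValueError(f"no group matching {group_match!r}")
    return round(100.0 * sub.n_mutated.sum() / sub.n_cases.sum(), 1)


def _round_sf(x: float, sf: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sf - 1)


def reproduce_cohort_stats() -> pd.DataFrame:
    """Recompute published rates and the Fisher test; emit a pass/fail table."""
    t1 = load_table1()
    cohort = load_cohort32()
    table = tp53_cin_table(cohort)
    checks = [
        ("n_cin_high", int((cohort.cin_category == "High").sum()), EXPECTED["n_cin_high"]),
        ("n_cin_low", int((cohort.cin_category == "Low").sum()), EXPECTED["n_cin_low"]),
        ("n_tp53_loss", int((cohort.tp53_status == "LOSS").sum()), EXPECTED["n_tp53_loss"]),
        ("loss_rate_high_pct", loss_rate_pct(cohort, "High"), EXPECTED["loss_rate_high_pct"]),
        ("loss_rate_low_pct", loss_rate_pct(cohort, "Low"), EXPECTED["loss_rate_low_pct"]),
        ("fisher_p_2sf", _round_sf(fisher_exact_2x2(table), 2), EXPECTED["fisher_p_2sf"]),
        ("overall_mutation_rate_pct", mutation_rate_pct(t1), EXPECTED["overall_mutation_rate_pct"]),
        ("familial_mutation_rate_pct", mutation_rate_pct(t1, "Familial"), EXPECTED["familial_mutation_rate_pct"]),
    ]
    return pd.DataFrame(
        [
            {"statistic": name, "computed": got, "expected": want, "pass": got == want}
            for name, got, want in checks
        ]
    )
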