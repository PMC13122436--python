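"""End-to-end orchestration: simulate → reconstruct → classify → selection →
demography, plus the sampling-point summary table.

:func:`run_pipeline` drives every stage off one :class:`PipelineConfig` and
one seed, returning a bundle of tidy tables.  :func:`summarize_table2`
builds the per-region, per-year summary of natal-exit size and phenotype
fractions, with all-years aggregate rows computed as *unweighted means of
the annual values* (annual means and annual percentages averaged across
years, not pooled over fish — pooled means are available via a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backcalc import fl_from_radius, mass_apportionment, radius_from_fl
from .config import BackcalcParams, IsoscapeConfig, SimConfig
from .demography import build_cohort_table, cohort_replacement
from .phenotype import PhenotypeCutoff, classify_phenotype, density_crossing, dip_test, fit_mixture
from .profiles import reconstruct_exits
from .provenance import (
    AssignmentInput,
    assign_age,
    lens_prescreen,
    reassign_exogenous,
    standin_class_probabilities,
)
from .selection import segment_differentials
from .simulate import simulate_study

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "summarize_table2",
    "estimate_cutoff",
    "reconstruct_records",
    "apply_provenance",
]

REGION_ORDER = ["delta_entry", "delta_bay", "delta_exit", "spawning"]


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-study run."""

    sim: SimConfig = field(default_factory=SimConfig)
    iso: IsoscapeConfig = field(default_factory=IsoscapeConfig)
    backcalc: BackcalcParams = field(default_factory=BackcalcParams)
    years: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018)
    legacy_cutoff_mm: float = 55.0
    #: which sampling points' fish enter the pooled cutoff estimation
    standardize_by: str = "sd"
    dip_n_boot: int = 500
    seed: int = 0


def estimate_cutoff(natal_exit_fl, seed=0, n_boot=500) -> PhenotypeCutoff:
    """Pooled phenotype cutoff: dip test + mixture fit + density crossing."""
    x = np.asarray(natal_exit_fl, dtype=float)
    x = x[np.isfinite(x)]
    d, p = dip_test(x, n_boot=n_boot, seed=seed)
    fit = fit_mixture(x, seed=seed)
    cut = density_crossing(fit)
    return PhenotypeCutoff(
        cutoff_fl=cut,
        cutoff_radius=float(radius_from_fl(cut)),
        dip_statistic=d,
        dip_pvalue=p,
    )


def reconstruct_records(records, profiles, iso, params):
    """Attach natal/freshwater exit estimates (radius, FL, method) to records."""
    by_id = {p.fish_id: p for p in profiles}
    out = records.copy()
    cols = {
        "natal_exit_radius": [],
        "natal_exit_fl": [],
        "natal_exit_method": [],
        "fw_exit_radius": [],
        "fw_exit_fl": [],
        "fw_exit_method": [],
        "nonnatal_fraction": [],
    }
    for _, row in records.iterrows():
        prof = by_id[row.fish_id]
        point = row.collection_point
        if point in ("delta_entry", "delta_bay"):
            est = reconstruct_exits(prof, iso, context="juvenile-above-chipps")
            fw_r = fw_fl = np.nan
            fw_m = None
        elif point == "delta_exit":
            est = reconstruct_exits(prof, iso, context="juvenile-above-chipps")
            fw_r = np.nan
            fw_fl = row.fl_mm  # measured FL is the freshwater-exit size
            fw_m = "measured-FL"
        else:
            est = reconstruct_exits(prof, iso, context="adult-or-bay")
            fw_r = est.fw_exit_radius
            fw_fl = fl_from_radius(fw_r, params)
            fw_m = est.fw_exit_method
        natal_r = est.natal_exit_radius
        cols["natal_exit_radius"].append(natal_r)
        cols["natal_exit_fl"].append(fl_from_radius(natal_r, params))
        cols["natal_exit_method"].append(est.natal_exit_method)
        cols["fw_exit_radius"].append(fw_r)
        cols["fw_exit_fl"].append(fw_fl)
        cols["fw_exit_method"].append(fw_m)
        if point == "spawning" and natal_r >= params.emergence_radius:
            cols["nonnatal_fraction"].append(
                mass_apportionment(min(natal_r, fw_r), fw_r, params).nonnatal_fraction
            )
        else:
            cols["nonnatal_fraction"].append(np.nan)
    for k, v in cols.items():
        out[k] = v
    return out


def apply_provenance(records, profiles, iso):
    """δ³⁴S prescreen (adults), stand-in classifier + exogenous rule."""
    by_id = {p.fish_id: p for p in profiles}
    refs = {"AME": iso.ame_water_ratio, "NIH": iso.nih_water_ratio}
    out = records.copy()
    screens, sources = [], []
    for _, row in records.iterrows():
        screen = lens_prescreen(None if pd.isna(row.lens_d34s) else float(row.lens_d34s))
        if row.collection_point == "spawning" and screen == "hatchery":
            screens.append(screen)
            sources.append("hatchery-lens")
            continue
        probs = standin_class_probabilities(by_id[row.fish_id], refs)
        res = reassign_exogenous(
            AssignmentInput(
                fish_id=row.fish_id,
                class_probabilities=probs,
                exo_score=float(row.exo_score),
            )
        )
        screens.append(screen)
        sources.append(res.final_source)
    out["lens_screen"] = screens
    out["assigned_source"] = sources
    out["assigned_age"] = [
        assign_age(row.scale_age, row.fl_mm / 10.0) if row.collection_point == "spawning" else np.nan
        for _, row in out.iterrows()
    ]
    return out


def summarize_table2(
    records: pd.DataFrame,
    cutoff_fl: float,
    legacy_cutoff_fl: float = 55.0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-region, per-year summary with an all-years aggregate row.

    All-years rows are unweighted means of the annual means/percentages
    (``pooled=True`` instead pools fish across years).
    """
    if records.empty:
        raise ValueError("no records to summarise")
    rows = []
    for region, rgrp in records.groupby("collection_point", sort=False):
        for year, grp in rgrp.groupby("outmigration_year"):
            natal = grp["natal_exit_fl"].dropna()
            fw = grp["fw_exit_fl"].dropna() if "fw_exit_fl" in grp else pd.Series(dtype=float)
            rows.append(
                {
                    "region": region,
                    "outmigration_year": int(year),
                    "n": int(len(natal)),
                    "natal_mean_mm": natal.mean(),
                    "natal_sd_mm": natal.std(ddof=1),
                    "pct_early": 100.0 * np.mean(natal <= cutoff_fl) if len(natal) else np.nan,
                    "pct_early_legacy": 100.0 * np.mean(natal <= legacy_cutoff_fl)
                    if len(natal)
                    else np.nan,
                    "fw_mean_mm": fw.mean() if len(fw) else np.nan,
                    "fw_sd_mm": fw.std(ddof=1) if len(fw) > 1 else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    agg_rows = []
    for region, grp in df.groupby("region", sort=False):
        if pooled:
            sub = records[records.collection_point == region]
            natal = sub["natal_exit_fl"].dropna()
            fw = sub["fw_exit_fl"].dropna()
            agg = {
                "natal_mean_mm": natal.mean(),
                "natal_sd_mm": natal.std(ddof=1),
                "pct_early": 100.0 * np.mean(natal <= cutoff_fl),
                "pct_early_legacy": 100.0 * np.mean(natal <= legacy_cutoff_fl),
                "fw_mean_mm": fw.mean() if len(fw) else np.nan,
                "fw_sd_mm": fw.std(ddof=1) if len(fw) > 1 else np.nan,
            }
        else:
            agg = {
                "natal_mean_mm": grp["natal_mean_mm"].mean(),
                "natal_sd_mm": grp["natal_mean_mm"].std(ddof=1),
                "pct_early": grp["pct_early"].mean(),
                "pct_early_legacy": grp["pct_early_legacy"].mean(),
                "fw_mean_mm": grp["fw_mean_mm"].mean(),
                "fw_sd_mm": grp["fw_mean_mm"].std(ddof=1),
            }
        agg_rows.append({"region": region, "outmigration_year": None, "n": int(grp["n"].sum()), **agg})
    return pd.concat([df, pd.DataFrame(agg_rows)], ignore_index=True)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full synthetic-study analysis; optionally write CSV/JSON.

    Stages: cohort simulation → per-fish exit reconstruction →
    back-calculation and mass apportionment → provenance screening →
    pooled phenotype cutoff → sampling-point summaries → selection
    differentials → cohort demography.  Deterministic for a fixed config.
    """
    rng_seed = config.seed
    histories, profiles, records = simulate_study(
        config.sim, config.iso, years=config.years, seed=rng_seed
    )
    records = reconstruct_records(records, profiles, config.iso, config.backcalc)
    records = apply_provenance(records, profiles, config.iso)

    # analysis set: fish assigned to the wild natal source
    wild = records[records.assigned_source == "AME"].copy()
    cutoff = estimate_cutoff(
        wild["natal_exit_fl"].dropna(), seed=rng_seed, n_boot=config.dip_n_boot
    )
    wild["phenotype"] = classify_phenotype(wild["natal_exit_fl"].to_numpy(), cutoff.cutoff_fl)

    summary = summarize_table2(wild, cutoff.cutoff_fl, config.legacy_cutoff_mm)
    # adults carry their cohort-matched outmigration year (escapement − age + 1)
    wild_adults = wild.collection_point == "spawning"
    wild.loc[wild_adults, "outmigration_year"] = (
        wild.loc[wild_adults, "escapement_year"] - wild.loc[wild_adults, "assigned_age"] + 1
    )
    selection = segment_differentials(wild, standardize_by=config.standardize_by)

    # demography from the adult sample composition
    adults = records[records.collection_point == "spawning"]
    esc, nh, nw = {}, {}, {}
    for year, grp in adults.groupby("escapement_year"):
        y = int(year)
        nh[y] = int((grp.assigned_source != "AME").sum())
        nw[y] = int((grp.assigned_source == "AME").sum())
        esc[y] = float(len(grp)) / 0.01  # stand-in total escapement scale
    cohort = (
        build_cohort_table(esc, nh, nw, marking_rate=config.sim.marking_rate)
        if esc
        else pd.DataFrame()
    )

    bundle = {
        "records": records,
        "analysis_records": wild,
        "cutoff": cutoff,
        "summary": summary,
        "selection": selection,
        "cohort_table": cohort,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records.to_csv(outdir / "fish_records.csv", index=False)
        summary.to_csv(outdir / "sampling_point_summary.csv", index=False)
        selection.to_csv(outdir / "selection_differentials.csv", index=False)
        cohort.to_csv(outdir / "cohort_table.csv")
    return bundle
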