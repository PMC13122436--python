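"""Standardized selection differentials between sequential sampling points.

The selection differential on natal-exit size between an initial population
and its survivors is

    i = (z̄*_t − z̄_t) / s_t

where z̄_t and z̄*_t are the initial and surviving mean fork lengths and s_t
standardises the shift.  The default standardisation divides by the initial
sample's **standard deviation** — the classical standardized differential,
and the scaling that reproduces the published per-segment values — with the
initial-sample **variance** available as a config option
(``standardize_by="variance"``), since the defining equation is sometimes
written that way.  Positive i means smaller outmigrants survived worse.

Segments:

* ``Delta`` — juveniles entering vs. leaving the Delta, same outmigration year;
* ``Ocean`` — juveniles leaving the Delta vs. cohort-matched adults
  (escapement year − age + 1 = outmigration year);
* ``All``   — juveniles entering the Delta vs. cohort-matched adults.

Also provides the catch-expansion sensitivity resampler, which re-weights
otolith-sampled fish to mimic the observed catch distribution over time bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SelectionResult",
    "selection_differential",
    "segment_differentials",
    "regress_i",
    "expand_to_catch",
]

Standardize = Literal["sd", "variance"]


@dataclass
class SelectionResult:
    """One segment-year selection differential and its components."""

    segment: str
    year: int | None
    i: float
    z_bar_init: float
    z_bar_surv: float
    v_init: float  # initial-sample variance (mm², n−1 denominator)
    n_init: int
    n_surv: int
    standardize_by: str = "sd"


def selection_differential(
    init_sizes,
    surv_sizes,
    segment: str = "All",
    year: int | None = None,
    standardize_by: Standardize = "sd",
) -> SelectionResult:
    """Standardized selection differential between a population and its survivors."""
    z0 = np.asarray(init_sizes, dtype=float)
    z1 = np.asarray(surv_sizes, dtype=float)
    if z0.size < 2 or z1.size < 1:
        raise ValueError("need >=2 initial and >=1 surviving observations")
    v = float(np.var(z0, ddof=1))
    if v <= 0:
        raise ValueError("initial sample has zero variance")
    denom = np.sqrt(v) if standardize_by == "sd" else v
    return SelectionResult(
        segment=segment,
        year=year,
        i=float((z1.mean() - z0.mean()) / denom),
        z_bar_init=float(z0.mean()),
        z_bar_surv=float(z1.mean()),
        v_init=v,
        n_init=int(z0.size),
        n_surv=int(z1.size),
        standardize_by=standardize_by,
    )


#: which collection points bound each segment
SEGMENTS = {
    "Delta": ("delta_entry", "delta_exit"),
    "Ocean": ("delta_exit", "spawning"),
    "All": ("delta_entry", "spawning"),
}


def segment_differentials(
    records: pd.DataFrame,
    size_col: str = "natal_exit_fl",
    standardize_by: Standardize = "sd",
    segments: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-year Delta / Ocean / All differentials from a fish-record table.

    ``records`` needs columns ``collection_point``, ``outmigration_year``
    and the natal-exit size column.  Adults must already carry their
    cohort-matched outmigration year.  Years missing either endpoint of a
    segment are skipped.
    """
    segments = segments or SEGMENTS
    rows = []
    for seg, (p0, p1) in segments.items():
        for year, grp in records.groupby("outmigration_year"):
            z0 = grp.loc[grp.collection_point == p0, size_col].dropna()
            z1 = grp.loc[grp.collection_point == p1, size_col].dropna()
            if len(z0) < 2 or len(z1) < 1:
                continue
            res = selection_differential(
                z0, z1, segment=seg, year=int(year), standardize_by=standardize_by
            )
            rows.append(vars(res))
    return pd.DataFrame(rows)


def regress_i(
    i_values,
    covariate,
    form: Literal["linear", "quadratic"] = "linear",
):
    """OLS of selection differentials (or any response) on one covariate.

    ``quadratic`` fits intercept + x + x².  Returns the fitted statsmodels
    results object (coefficients, F, p, adjusted R²).
    """
    y = np.asarray(i_values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if form == "linear":
        X = sm.add_constant(x)
        k = 1
    elif form == "quadratic":
        X = sm.add_constant(np.column_stack([x, x**2]))
        k = 2
    else:
        raise ValueError(f"unknown form {form!r}")
    if y.size < k + 2:
        raise ValueError(f"need at least {k + 2} observations for {form} fit")
    return sm.OLS(y, X).fit()


def expand_to_catch(
    otolith_sample: pd.DataFrame,
    catch_counts: pd.Series | dict,
    bin_months: int = 1,
    month_col: str = "sample_month",
    seed: int | np.random.Generator | None = 0,
    total: int | None = None,
) -> pd.DataFrame:
    """Resample otolith-sampled fish to mimic the observed catch distribution.

    Months are grouped into bins of ``bin_months``; within each bin, sampled
    fish are drawn with replacement in proportion to that bin's total catch.
    A catch bin with no otolith samples is merged into the subsequent bin
    (and the trailing remainder backward).  The expanded sample has
    ``total`` rows (default: the total catch).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    catch = pd.Series(catch_counts, dtype=float)
    months = sorted(catch.index)
    bins = {m: (m - min(months)) // bin_months for m in months}
    sample_bins = otolith_sample[month_col].map(bins)
    catch_by_bin: dict[int, float] = {}
    for m in months:
        catch_by_bin[bins[m]] = catch_by_bin.get(bins[m], 0.0) + float(catch[m])

    # merge catch bins lacking samples into the subsequent bin
    ordered = sorted(catch_by_bin)
    have = set(sample_bins.dropna().unique())
    merged: dict[int, float] = {}
    carry = 0.0
    for b in ordered:
        c = catch_by_bin[b] + carry
        carry = 0.0
        if b in have:
            merged[b] = c
        elif c > 0:
            carry = c
    if carry > 0:
        if not merged:
            raise ValueError("catch observed but no otolith samples in any bin")
        merged[max(merged)] += carry

    total_catch = sum(merged.values())
    if total is None:
        total = int(round(total_catch))
    out = []
    for b, c in merged.items():
        k = int(round(total * c / total_catch))
        pool = otolith_sample[sample_bins == b]
        if k > 0:
            out.append(pool.sample(n=k, replace=True, random_state=rng))
    return pd.concat(out, ignore_index=True) if out else otolith_sample.iloc[0:0]
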