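"""Cohort demography: hatchery/wild composition and replacement rates.

Carcass surveys only sample unmarked fish, but a known fraction of hatchery
releases (the marking rate, typically 25%) carry a clipped adipose fin, so
the hatchery-assigned sample count is expanded by 1/(1 − marking_rate)
(= 1.33 at a 25% rate) before computing composition.  Natural-origin
escapement is total escapement times the natural fraction, and the cohort
replacement rate (CRR) of a brood year B is

    CRR(B) = Σ_{a∈{2,3,4}} E_nat(B + a) · f_a(B + a) / E_nat(B)

with f_a the age-a fraction of returns in each escapement year (imputed
with the cross-year mean where missing).  CRR > 1 implies positive
population growth.  Internal arithmetic uses the exact reciprocal
1/(1 − marking_rate); the conventional printed factor 1.33 is display
rounding only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .selection import regress_i

__all__ = [
    "hatchery_fraction",
    "natural_escapement",
    "cohort_replacement",
    "crr_flow_regression",
    "build_cohort_table",
]

AGES = (2, 3, 4)


def hatchery_fraction(
    n_hatchery_assigned: float, n_wild_assigned: float, marking_rate: float = 0.25
) -> float:
    """Hatchery fraction of spawners after expanding for unsampled marked fish."""
    if n_hatchery_assigned < 0 or n_wild_assigned < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= marking_rate < 1.0:
        raise ValueError("marking_rate must lie in [0, 1)")
    if n_hatchery_assigned == 0 and n_wild_assigned == 0:
        raise ValueError("no assigned fish")
    expanded = n_hatchery_assigned / (1.0 - marking_rate)
    return expanded / (expanded + n_wild_assigned)


def natural_escapement(total_escapement: float, fraction_hatchery: float) -> float:
    """Natural-origin spawner count: total escapement × (1 − hatchery fraction)."""
    return total_escapement * (1.0 - fraction_hatchery)


def build_cohort_table(
    escapement: dict[int, float],
    n_hatchery_assigned: dict[int, float],
    n_wild_assigned: dict[int, float],
    age_fractions: dict[int, tuple[float, float, float]] | None = None,
    marking_rate: float = 0.25,
) -> pd.DataFrame:
    """Assemble the per-escapement-year cohort table.

    ``age_fractions`` maps escapement year → (age2, age3, age4) fractions of
    returns; years absent from the map get the cross-year mean imputed (all
    years absent → flagged error at CRR time).
    """
    years = sorted(escapement)
    rows = []
    for y in years:
        fh = hatchery_fraction(n_hatchery_assigned[y], n_wild_assigned[y], marking_rate)
        af = age_fractions.get(y) if age_fractions else None
        rows.append(
            {
                "escapement_year": y,
                "total_escapement": float(escapement[y]),
                "n_hatchery_assigned": float(n_hatchery_assigned[y]),
                "n_wild_assigned": float(n_wild_assigned[y]),
                "fraction_hatchery": fh,
                "natural_escapement": natural_escapement(escapement[y], fh),
                "age2_frac": np.nan if af is None else af[0],
                "age3_frac": np.nan if af is None else af[1],
                "age4_frac": np.nan if af is None else af[2],
            }
        )
    df = pd.DataFrame(rows).set_index("escapement_year")
    for col in ("age2_frac", "age3_frac", "age4_frac"):
        if df[col].notna().any():
            df[col] = df[col].fillna(df[col].mean())
    known = df[["age2_frac", "age3_frac", "age4_frac"]].notna().all(axis=1)
    sums = df.loc[known, ["age2_frac", "age3_frac", "age4_frac"]].sum(axis=1)
    if known.any() and not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("age fractions must sum to 1 per year")
    return df


def cohort_replacement(
    table: pd.DataFrame, brood_year: int, age3_only: bool = False
) -> float:
    """Cohort replacement rate of natural-origin fish for one brood year.

    Needs natural escapement for the brood year and escapement years
    brood+2..brood+4.  With ``age3_only`` every return is attributed to age
    3 (the assumption-light variant): CRR = E_nat(brood+3)/E_nat(brood).
    """
    if brood_year not in table.index:
        raise ValueError(f"no escapement row for brood year {brood_year}")
    spawners = float(table.loc[brood_year, "natural_escapement"])
    if spawners <= 0:
        raise ValueError("zero natural spawners in brood year")
    if age3_only:
        ry = brood_year + 3
        if ry not in table.index:
            raise ValueError(f"missing return year {ry}")
        return float(table.loc[ry, "natural_escapement"]) / spawners
    returns = 0.0
    for a in AGES:
        ry = brood_year + a
        if ry not in table.index:
            raise ValueError(f"missing return year {ry}")
        frac = float(table.loc[ry, f"age{a}_frac"])
        if np.isnan(frac):
            raise ValueError(f"age fractions unavailable for {ry}")
        returns += float(table.loc[ry, "natural_escapement"]) * frac
    return returns / spawners


def crr_flow_regression(crr_values, flows, form: str = "quadratic"):
    """OLS of cohort replacement rate on mean Jan–June flow (and flow²)."""
    y = np.asarray(crr_values, dtype=float)
    x = np.asarray(flows, dtype=float)
    if form == "quadratic" and y.size < 5:
        raise ValueError("need at least 5 points for the quadratic fit")
    return regress_i(y, x, form=form)
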