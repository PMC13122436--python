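"""Synthetic cohort generator.

Generates complete, internally consistent datasets — true life histories,
observed otolith chemical transects, and lethal catches at sequential
sampling points — with the statistical structure the downstream analysis
assumes:

* natal-exit fork lengths from a two-component (fry/smolt) normal mixture;
* unimodal ocean-entry sizes centred on 80.1 ± 9.38 mm;
* otolith ⁸⁷Sr/⁸⁶Sr transects that start on the natal-river value, dip to
  the Delta value during non-natal rearing, and rise to the marine value
  after freshwater exit, with SrV rising from a freshwater baseline to a
  marine plateau;
* logistic size-selective survival through the Delta and the ocean, making
  each sampling point a survivor subset of the previous one;
* a hatchery component (release-sized smolts, marine-feed eye-lens δ³⁴S,
  partial fin-clip marking).

The generator is the exact inverse of the reconstruction: the noiseless
ratio transect crosses the natal-exit threshold precisely at the radius
corresponding to the true natal-exit size, and the estuary threshold (or
the normalised-SrV fraction, for rapid migrants) precisely at the
freshwater-exit radius.  Every draw flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backcalc import radius_from_fl
from .config import IsoscapeConfig, SimConfig
from .profiles import ChemProfile

__all__ = [
    "TrueHistory",
    "simulate_cohort",
    "profile_from_history",
    "simulate_study",
    "SAMPLING_POINTS",
]

#: ordered sampling points along the migratory corridor
SAMPLING_POINTS = ("delta_entry", "delta_bay", "delta_exit", "spawning")

#: stages a fish can survive to (the seine samples Delta residents and is
#: not itself a survival stage)
_STAGES = ("delta_entry", "delta_exit", "spawning")


@dataclass
class TrueHistory:
    """Ground-truth life history of one simulated fish."""

    fish_id: str
    origin: str  # natal-river-wild | natal-hatchery | other
    phenotype_true: str  # early | late
    natal_exit_fl_true: float
    freshwater_exit_fl_true: float
    natal_exit_radius_true: float
    fw_exit_radius_true: float
    survived_to: str
    age_at_return: int
    lens_d34s_true: float
    fin_clipped: bool
    exo_score: float
    year: int


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def _truncated_normal(rng, mean, sd, lower, size):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.maximum(out, lower)


def simulate_cohort(
    cfg: SimConfig,
    iso: IsoscapeConfig | None = None,
    year: int = 2014,
    rng: np.random.Generator | None = None,
) -> tuple[list[TrueHistory], list[ChemProfile], pd.DataFrame]:
    """Simulate one outmigration cohort.

    Returns the full list of true histories, the chemical transects of the
    *caught* fish (profiles are only measured on sampled fish, as in the
    field), and the tidy catch-record table (one row per sampled fish).
    """
    iso = iso or IsoscapeConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_fish

    hatchery = rng.random(n) < cfg.hatchery_fraction
    early = (~hatchery) & (rng.random(n) < cfg.early_weight)
    # natal-exit FL: wild fish from the fry/smolt mixture, hatchery fish at
    # release size (they leave the river as released smolts)
    natal_fl = np.empty(n)
    natal_fl[early] = _truncated_normal(
        rng, cfg.early_mean_fl, cfg.early_sd_fl, cfg.min_natal_exit_fl, int(early.sum())
    )
    late_wild = (~hatchery) & (~early)
    natal_fl[late_wild] = _truncated_normal(
        rng, cfg.late_mean_fl, cfg.late_sd_fl, cfg.min_natal_exit_fl, int(late_wild.sum())
    )
    natal_fl[hatchery] = _truncated_normal(
        rng,
        cfg.hatchery_release_mean_fl,
        cfg.hatchery_release_sd_fl,
        cfg.min_natal_exit_fl,
        int(hatchery.sum()),
    )

    # freshwater-exit FL: ocean-entry draw for fish that rear in the Delta;
    # rapid late migrants (and hatchery smolts trucked downstream) leave at
    # their natal-exit size
    ocean_draw = rng.normal(cfg.ocean_entry_mean_fl, cfg.ocean_entry_sd_fl, n)
    rapid = np.zeros(n, dtype=bool)
    rapid[late_wild] = rng.random(int(late_wild.sum())) < cfg.rapid_migrant_fraction
    rapid[hatchery] = True
    fw_fl = np.where(rapid, natal_fl, np.maximum(ocean_draw, natal_fl + cfg.min_delta_growth_fl))

    # size-selective survival acting on natal-exit FL
    z = natal_fl - cfg.selection_reference_fl
    p_delta = _logistic(_logit(cfg.delta_base_survival) + cfg.delta_selection_slope * z)
    p_ocean = _logistic(_logit(cfg.ocean_base_survival) + cfg.ocean_selection_slope * z)
    reached_exit = rng.random(n) < p_delta
    reached_spawn = reached_exit & (rng.random(n) < p_ocean)

    age = rng.choice([2, 3, 4], size=n, p=list(cfg.age_probs))
    lens = np.where(
        hatchery,
        rng.normal(cfg.lens_hatchery_mean, cfg.lens_hatchery_sd, n),
        rng.normal(cfg.lens_wild_mean, cfg.lens_wild_sd, n),
    )
    clipped = hatchery & (rng.random(n) < cfg.marking_rate)
    # exogenous feeding check: sharp (2) in most wild fish, indistinct (1)
    # in most hatchery fish, 1.5 = unscorable
    exo = np.where(
        hatchery,
        rng.choice([1.0, 1.5, 2.0], size=n, p=[0.7, 0.2, 0.1]),
        rng.choice([1.0, 1.5, 2.0], size=n, p=[0.1, 0.2, 0.7]),
    )

    natal_r = radius_from_fl(natal_fl)
    fw_r = radius_from_fl(fw_fl)
    survived_to = np.where(reached_spawn, "spawning", np.where(reached_exit, "delta_exit", "delta_entry"))

    histories = [
        TrueHistory(
            fish_id=f"{year}-{i:05d}",
            origin="natal-hatchery" if hatchery[i] else "natal-river-wild",
            phenotype_true="early" if early[i] else "late",
            natal_exit_fl_true=float(natal_fl[i]),
            freshwater_exit_fl_true=float(fw_fl[i]),
            natal_exit_radius_true=float(natal_r[i]),
            fw_exit_radius_true=float(fw_r[i]),
            survived_to=str(survived_to[i]),
            age_at_return=int(age[i]),
            lens_d34s_true=float(lens[i]),
            fin_clipped=bool(clipped[i]),
            exo_score=float(exo[i]),
            year=year,
        )
        for i in range(n)
    ]

    records, profiles = _catch_and_measure(
        histories, cfg, iso, rng, early=early, rapid=rapid, clipped=clipped
    )
    return histories, profiles, records


def _catch_and_measure(histories, cfg, iso, rng, early, rapid, clipped):
    """Lethal sampling at each point, then transect measurement of the catch."""
    n = len(histories)
    caught = np.zeros(n, dtype=bool)
    reached_exit = np.array([h.survived_to in ("delta_exit", "spawning") for h in histories])
    reached_spawn = np.array([h.survived_to == "spawning" for h in histories])
    rows = []
    profiles = []

    def sample(eligible: np.ndarray, k: int, weights=None) -> np.ndarray:
        idx = np.flatnonzero(eligible & ~caught)
        if idx.size == 0 or k <= 0:
            return np.array([], dtype=int)
        k = min(k, idx.size)
        if weights is not None:
            w = weights[idx] / weights[idx].sum()
            chosen = rng.choice(idx, size=k, replace=False, p=w)
        else:
            chosen = rng.choice(idx, size=k, replace=False)
        caught[chosen] = True
        return chosen

    # juvenile monitoring only retains unmarked fish
    unmarked = ~clipped

    def add_records(chosen, point):
        for i in chosen:
            h = histories[i]
            rows.append(_record_row(h, point, cfg, rng))
            profiles.append(profile_from_history(h, iso, cfg, rng=rng, caught_at=point))

    add_records(sample(unmarked, cfg.n_catch_entry), "delta_entry")
    seine_w = np.where(early, cfg.seine_early_bias, 1.0) * (~rapid)
    add_records(sample(unmarked & (seine_w > 0), cfg.n_catch_seine, weights=seine_w), "delta_bay")
    add_records(sample(unmarked & reached_exit, cfg.n_catch_exit), "delta_exit")
    # carcass surveys skip fin-clipped (marked hatchery) adults
    add_records(sample(unmarked & reached_spawn, cfg.n_catch_spawn), "spawning")

    records = pd.DataFrame(rows)
    return records, profiles


def _record_row(h: TrueHistory, point: str, cfg: SimConfig, rng) -> dict:
    is_adult = point == "spawning"
    if point == "delta_entry":
        fl = h.natal_exit_fl_true
        month = 1 + int(rng.integers(0, 2)) if h.phenotype_true == "early" else 4 + int(rng.integers(0, 2))
    elif point == "delta_bay":
        fl = 0.5 * (h.natal_exit_fl_true + h.freshwater_exit_fl_true)
        month = 2 + int(rng.integers(0, 3))
    elif point == "delta_exit":
        fl = h.freshwater_exit_fl_true
        month = 4 + int(rng.integers(0, 3))
    else:
        # adult FL (cm) scales with return age
        fl = float(rng.normal({2: 55, 3: 80, 4: 105}[h.age_at_return], 5.0)) * 10.0
        month = 11
    esc_year = h.year + h.age_at_return - 1 if is_adult else np.nan
    scale_age = h.age_at_return if (is_adult and rng.random() < 0.6) else np.nan
    return {
        "fish_id": h.fish_id,
        "collection_point": point,
        "outmigration_year": h.year,
        "escapement_year": esc_year,
        "sample_month": month,
        "fl_mm": float(fl),
        "sex": rng.choice(["F", "M"]),
        "scale_age": scale_age,
        "lens_d34s": h.lens_d34s_true + float(rng.normal(0, 0.3)) if is_adult else np.nan,
        "fin_clipped": h.fin_clipped,
        "exo_score": h.exo_score,
        "origin_true": h.origin,
        "phenotype_true": h.phenotype_true,
    }


def _ramp(r, r0, r1, y0, y1):
    """Piecewise-linear transition y0→y1 over [r0, r1], constant outside."""
    t = np.clip((r - r0) / max(r1 - r0, 1e-12), 0.0, 1.0)
    return y0 + (y1 - y0) * t


def profile_from_history(
    h: TrueHistory,
    iso: IsoscapeConfig | None = None,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | int | None = None,
    caught_at: str = "spawning",
    noise_sd: float | None = None,
) -> ChemProfile:
    """Forward-model one fish's otolith transect from its true history.

    The noiseless ⁸⁷Sr/⁸⁶Sr series crosses ``ame_min_ratio`` downward exactly
    at the true natal-exit radius and ``chipps_mean_ratio`` upward exactly at
    the true freshwater-exit radius; the SrV ramp passes the configured
    fraction of its range exactly at the freshwater-exit radius.  Rapid
    migrants (natal exit = freshwater exit) never visit the Delta value, so
    their ratio series stays above both thresholds — the case the SrV
    fallback exists for.  The transect is truncated at a radius set by where
    the fish was caught.
    """
    iso = iso or IsoscapeConfig()
    cfg = cfg or SimConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if noise_sd is None:
        noise_sd = iso.measurement_sd
    if h.natal_exit_fl_true > h.freshwater_exit_fl_true:
        raise ValueError("natal exit cannot exceed freshwater exit")
    if h.natal_exit_fl_true < 31.1:
        raise ValueError("exit FL below emergence size of the back-calculation model")

    base = iso.nih_water_ratio if h.origin == "natal-hatchery" else iso.ame_water_ratio
    r_natal = h.natal_exit_radius_true
    r_fw = h.fw_exit_radius_true
    rearing = r_fw > r_natal + 1e-9
    lag = cfg.transition_lag_um
    step = cfg.measurement_step_um

    if rearing:
        frac_down = (base - iso.ame_min_ratio) / (base - iso.delta_water_ratio)
        frac_up = (iso.chipps_mean_ratio - iso.delta_water_ratio) / (
            iso.ocean_ratio - iso.delta_water_ratio
        )
        # shrink the ramps if Delta residence is too short for both
        lag_eff = min(lag, (r_fw - r_natal) / (frac_up + (1.0 - frac_down)) * 0.95)
        r_d0 = r_natal - lag_eff * frac_down
        r_d1 = r_d0 + lag_eff
        r_u0 = r_fw - lag_eff * frac_up
        r_u1 = r_u0 + lag_eff
    else:
        # straight transition natal-river → ocean around the (joint) exit
        r_d0 = r_d1 = None
        r_u0 = r_fw
        r_u1 = r_fw + lag

    # SrV: freshwater baseline → marine plateau, hitting the configured
    # fraction of the range exactly at the freshwater-exit radius
    srv_lo, srv_hi = 1.0, 3.0
    r_s0 = r_fw - lag * iso.srv_exit_fraction
    r_s1 = r_s0 + lag

    end_by_point = {
        # caught just before the otolith registers the Delta drop
        "delta_entry": (r_d0 if rearing else r_natal + 5.0),
        "delta_bay": (0.5 * (r_d1 + r_u0) if rearing else r_natal + 5.0),
        "delta_exit": r_fw + 5.0,
        "spawning": min(cfg.adult_truncation_radius_um, r_u1 + 150.0),
    }
    end = float(end_by_point[caught_at])
    start = 120.0
    radii = np.arange(start, end + 1e-9, step)
    if radii.size < 2:
        radii = np.array([start, end])

    if rearing:
        ratio = np.full(radii.size, base)
        ratio = np.where(
            radii >= r_d0, _ramp(radii, r_d0, r_d1, base, iso.delta_water_ratio), ratio
        )
        ratio = np.where(
            radii >= r_u0, _ramp(radii, r_u0, r_u1, iso.delta_water_ratio, iso.ocean_ratio), ratio
        )
    else:
        ratio = _ramp(radii, r_u0, r_u1, base, iso.ocean_ratio)

    srv = _ramp(radii, r_s0, r_s1, srv_lo, srv_hi)
    if caught_at in ("delta_entry", "delta_bay"):
        srv = np.full(radii.size, srv_lo)  # still in freshwater

    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, radii.size)
        srv = srv + rng.normal(0.0, 0.02, radii.size)

    return ChemProfile(
        fish_id=h.fish_id,
        radius_um=radii,
        sr_ratio=ratio,
        sr_ratio_2se=np.full(radii.size, 2.0 * max(noise_sd, 2e-5)),
        srv=srv,
        total_radius_um=float(radii[-1]),
    )


def simulate_study(
    cfg: SimConfig,
    iso: IsoscapeConfig | None = None,
    years: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018),
    seed: int | None = None,
) -> tuple[list[TrueHistory], list[ChemProfile], pd.DataFrame]:
    """Simulate several outmigration cohorts under one master seed."""
    iso = iso or IsoscapeConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    all_h, all_p, frames = [], [], []
    for year in years:
        h, p, r = simulate_cohort(cfg, iso, year=year, rng=rng)
        all_h.extend(h)
        all_p.extend(p)
        frames.append(r)
    return all_h, all_p, pd.concat(frames, ignore_index=True)
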