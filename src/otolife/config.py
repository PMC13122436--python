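"""Configuration objects shared across the reconstruction pipeline.

Three small parameter bundles drive everything:

* :class:`IsoscapeConfig` — the water ⁸⁷Sr/⁸⁶Sr reference values that turn an
  otolith transect into habitat transitions (natal river floor, estuary
  boundary mean, ocean value) plus the normalised-SrV fallback threshold.
* :class:`BackcalcParams` — the broken-stick otolith-radius→fork-length
  regression, the emergence baseline, and the radius→mass model used for
  habitat mass apportionment.
* :class:`SimConfig` — parameters of the synthetic cohort generator.

All three round-trip through plain dicts / YAML so a whole run is describable
by a single config file and a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import yaml


@dataclass
class IsoscapeConfig:
    """Water isotope reference values and reconstruction thresholds.

    Parameters
    ----------
    ame_min_ratio:
        Minimum water ⁸⁷Sr/⁸⁶Sr observed in the natal (American) river. The
        natal river sits isotopically above every other salmon river in the
        basin, so the first downward crossing of this value marks natal exit.
    chipps_mean_ratio:
        Mean ⁸⁷Sr/⁸⁶Sr at the Delta exit (Chipps Island); the first upward
        crossing after natal exit marks freshwater exit.
    ocean_ratio:
        Global marine ⁸⁷Sr/⁸⁶Sr (~0.70918); profiles plateau here after
        ocean entry.
    delta_water_ratio:
        Representative freshwater-Delta ratio used only by the synthetic
        generator. Must sit below ``chipps_mean_ratio`` so that both the
        downward natal crossing and the upward estuary crossing exist.
    srv_exit_fraction:
        Fraction of the normalised within-fish SrV range whose upward
        crossing is used as the freshwater-exit fallback when the ratio
        never crosses ``chipps_mean_ratio``.
    measurement_sd:
        Gaussian noise scale (isotope-ratio units) for simulated profiles.
    ame_water_ratio:
        Generator-only: the natal-river water value written into synthetic
        profiles. Must exceed ``ame_min_ratio``.
    nih_water_ratio:
        Generator-only: the on-river hatchery water value for synthetic
        hatchery fish; between ``ame_min_ratio`` and ``ame_water_ratio`` so
        hatchery profiles are close to, but separable from, wild ones.
    """

    ame_min_ratio: float = 0.7085
    chipps_mean_ratio: float = 0.70785
    ocean_ratio: float = 0.70918
    delta_water_ratio: float = 0.7070
    srv_exit_fraction: float = 0.52
    measurement_sd: float = 0.0001
    ame_water_ratio: float = 0.7092
    nih_water_ratio: float = 0.70875

    def __post_init__(self) -> None:
        if not (
            self.delta_water_ratio
            < self.chipps_mean_ratio
            < self.ame_min_ratio
            < self.ocean_ratio
        ):
            raise ValueError(
                "isoscape ordering violated: require delta < chipps < ame_min < ocean"
            )
        if not 0.0 < self.srv_exit_fraction < 1.0:
            raise ValueError("srv_exit_fraction must lie in (0, 1)")
        if self.measurement_sd < 0:
            raise ValueError("measurement_sd must be non-negative")
        if self.ame_water_ratio <= self.ame_min_ratio:
            raise ValueError("ame_water_ratio must exceed ame_min_ratio")
        if not self.ame_min_ratio < self.nih_water_ratio < self.ame_water_ratio:
            raise ValueError("nih_water_ratio must lie between ame_min and ame_water")


@dataclass
class BackcalcParams:
    """Broken-stick OR→FL regression, emergence baseline, and mass model.

    The fork-length model is piecewise linear in otolith radius (OR, μm along
    the dorsal axis from the core) with a breakpoint at 256 μm.  The mass
    model is a configurable strictly increasing allometric curve
    ``mass = mass_a * FL(OR) ** mass_b`` (grams); only mass *fractions* are
    used downstream, which are invariant to ``mass_a``.

    The emergence baseline pairs a 215 μm radius with a 30 mm fish as the
    zero point for freshwater mass apportionment.  Note the FL regression
    itself evaluates 215 μm to ~35.7 mm; the published pairing is kept
    as-is for apportionment rather than forced onto the regression line.
    """

    fl_slope_small: float = 0.021259
    fl_intercept_small: float = 31.08748
    fl_slope_large: float = 0.165660
    fl_intercept_large: float = -5.8799
    breakpoint: float = 256.0
    emergence_radius: float = 215.0
    emergence_fl: float = 30.0
    mass_a: float = 1e-5
    mass_b: float = 3.0

    def __post_init__(self) -> None:
        if self.mass_a <= 0 or self.mass_b <= 0:
            raise ValueError("mass model must be strictly increasing (a, b > 0)")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The defaults encode the statistical structure the analysis assumes:
    a bimodal natal-exit size distribution (fry pulse around 38 mm, smolt
    pulse around 70 mm), a unimodal ocean-entry size distribution centred
    on 80.1 ± 9.38 mm, logistic size-selective survival between sequential
    sampling points, and a hatchery component separable by eye-lens δ³⁴S.
    """

    n_fish: int = 20000
    #: mixture weight of the early (fry) component at natal exit
    early_weight: float = 0.7
    early_mean_fl: float = 40.5
    early_sd_fl: float = 3.0
    late_mean_fl: float = 70.0
    late_sd_fl: float = 8.0
    #: ocean-entry (freshwater-exit) fork length distribution, mm
    ocean_entry_mean_fl: float = 80.1
    ocean_entry_sd_fl: float = 9.38
    #: logistic slope (per mm natal-exit FL) of survival through the Delta
    delta_selection_slope: float = 0.06
    #: logistic slope (per mm natal-exit FL) of survival through the ocean
    ocean_selection_slope: float = 0.03
    #: survival probability for a fish of the reference size (47 mm)
    delta_base_survival: float = 0.3
    ocean_base_survival: float = 0.03
    #: reference FL at which base survival applies, mm
    selection_reference_fl: float = 47.0
    #: fraction of late migrants that sprint to sea (no Delta residence;
    #: their profiles never cross either ratio threshold)
    rapid_migrant_fraction: float = 0.5
    hatchery_fraction: float = 0.5
    marking_rate: float = 0.25
    #: eye-lens δ³⁴S component means/SDs (‰): wild freshwater vs. marine feed
    lens_wild_mean: float = 7.0
    lens_wild_sd: float = 1.5
    lens_hatchery_mean: float = 14.0
    lens_hatchery_sd: float = 1.5
    #: laser-spot spacing along the transect, μm
    measurement_step_um: float = 10.0
    #: length of the isotopic transition ramps in the otolith, μm
    transition_lag_um: float = 30.0
    #: adult transects are truncated shortly after the ocean plateau, μm
    adult_truncation_radius_um: float = 1000.0
    age_probs: tuple[float, float, float] = (0.1, 0.7, 0.2)
    #: lethal catch sizes per sampling point (mirroring study sample sizes)
    n_catch_entry: int = 100
    n_catch_seine: int = 60
    n_catch_exit: int = 60
    n_catch_spawn: int = 400
    #: beach seines over-sample margin-rearing fry; relative catchability of
    #: early vs. late migrants in the seine sample
    seine_early_bias: float = 4.0
    #: minimum simulated natal-exit FL, mm; kept above the broken-stick
    #: branch joint (36.53 mm) so every size maps to a measurable
    #: post-emergence otolith radius
    min_natal_exit_fl: float = 36.6
    #: minimum Delta growth (mm FL) for fish that rear between natal and
    #: freshwater exit, so both isotopic transitions fit in the profile
    min_delta_growth_fl: float = 5.0
    #: hatchery release size distribution (smolts), mm
    hatchery_release_mean_fl: float = 75.0
    hatchery_release_sd_fl: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish <= 0:
            raise ValueError("n_fish must be positive")
        if not 0.0 < self.early_weight < 1.0:
            raise ValueError("early_weight must lie strictly in (0, 1)")
        for sd in (self.early_sd_fl, self.late_sd_fl, self.ocean_entry_sd_fl):
            if sd <= 0:
                raise ValueError("degenerate (zero-variance) mixture component")
        if not 0.0 <= self.marking_rate <= 1.0:
            raise ValueError("marking_rate must lie in [0, 1]")
        if not 0.0 <= self.hatchery_fraction <= 1.0:
            raise ValueError("hatchery_fraction must lie in [0, 1]")
        if abs(sum(self.age_probs) - 1.0) > 1e-6:
            raise ValueError("age_probs must sum to 1")


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def save_config(cfg, stream_or_path: IO | str | Path) -> None:
    """Serialise a config dataclass to YAML."""
    payload = {"type": type(cfg).__name__, "params": _to_dict(cfg)}
    if isinstance(stream_or_path, (str, Path)):
        with open(stream_or_path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
    else:
        yaml.safe_dump(payload, stream_or_path, sort_keys=False)


_TYPES = {"IsoscapeConfig": IsoscapeConfig, "BackcalcParams": BackcalcParams, "SimConfig": SimConfig}


def load_config(stream_or_path: IO | str | Path):
    """Load a config dataclass previously written by :func:`save_config`."""
    if isinstance(stream_or_path, (str, Path)):
        with open(stream_or_path) as fh:
            payload = yaml.safe_load(fh)
    else:
        payload = yaml.safe_load(stream_or_path)
    cls = _TYPES[payload["type"]]
    params = payload["params"]
    if cls is SimConfig and "age_probs" in params:
        params["age_probs"] = tuple(params["age_probs"])
    return cls(**params)
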