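"""Threshold analysis of otolith ⁸⁷Sr/⁸⁶Sr and SrV transects.

Life-history transitions are read off each fish's chemical transect:

* **natal exit** — first *downward* crossing of the natal-river minimum water
  ratio (0.7085).  The natal river sits isotopically above the rest of the
  basin, so leaving it drags the otolith ratio down.
* **freshwater exit** — first *upward* crossing, after natal exit, of the
  estuary-boundary mean ratio (0.70785); the profile then rises toward the
  marine value.  When the ratio never crosses (fish that sprinted to sea),
  the within-fish min-max normalised SrV series is used instead: ocean water
  is Sr-rich, so the upward crossing of a fixed fraction (default 0.52) of
  the normalised SrV range marks ocean entry.

Crossing radii are located by linear interpolation between neighbouring
measurements.  A measurement exactly at the threshold counts as a crossing at
that radius, which keeps the crossing radius continuous in the data.  Only
the first qualifying crossing is used; an optional minimum-run filter can
require ``k`` consecutive points beyond the threshold to discount transient
noise (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal

import numpy as np
import pandas as pd

from .config import IsoscapeConfig

__all__ = [
    "ChemProfile",
    "ExitEstimate",
    "find_crossing",
    "normalize_srv",
    "natal_exit",
    "freshwater_exit",
    "reconstruct_exits",
    "read_profiles_csv",
    "write_profiles_csv",
]

Direction = Literal["downward", "upward"]
Context = Literal["juvenile-above-chipps", "adult-or-bay", "rst-measured"]


@dataclass
class ChemProfile:
    """One fish's ordered otolith transect.

    Radii are μm from the core along the standardised dorsal axis and must be
    strictly increasing; ``sr_ratio`` is ⁸⁷Sr/⁸⁶Sr, ``sr_ratio_2se`` its
    analytical 2SE (carried through but not used in crossing detection), and
    ``srv`` the strontium-concentration proxy signal in instrument units.
    """

    fish_id: str
    radius_um: np.ndarray
    sr_ratio: np.ndarray
    sr_ratio_2se: np.ndarray | None = None
    srv: np.ndarray | None = None
    total_radius_um: float | None = None

    def __post_init__(self) -> None:
        self.radius_um = np.asarray(self.radius_um, dtype=float)
        self.sr_ratio = np.asarray(self.sr_ratio, dtype=float)
        if self.radius_um.size < 2:
            raise ValueError("profile needs at least 2 measurements")
        if self.radius_um.size != self.sr_ratio.size:
            raise ValueError("radius and ratio series differ in length")
        if np.any(np.diff(self.radius_um) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.sr_ratio_2se is not None:
            self.sr_ratio_2se = np.asarray(self.sr_ratio_2se, dtype=float)
        if self.srv is not None:
            self.srv = np.asarray(self.srv, dtype=float)
            if self.srv.size != self.radius_um.size:
                raise ValueError("srv series length mismatch")
        if self.total_radius_um is None:
            self.total_radius_um = float(self.radius_um[-1])
        elif self.total_radius_um < self.radius_um[-1]:
            raise ValueError("total_radius_um smaller than last measurement")

    def truncate(self, max_radius_um: float) -> "ChemProfile":
        """Return a copy keeping only measurements at or below a radius."""
        keep = self.radius_um <= max_radius_um
        return ChemProfile(
            fish_id=self.fish_id,
            radius_um=self.radius_um[keep],
            sr_ratio=self.sr_ratio[keep],
            sr_ratio_2se=None if self.sr_ratio_2se is None else self.sr_ratio_2se[keep],
            srv=None if self.srv is None else self.srv[keep],
            total_radius_um=min(self.total_radius_um, max_radius_um),
        )


@dataclass
class ExitEstimate:
    """Natal- and freshwater-exit radii with the method that produced each."""

    fish_id: str
    natal_exit_radius: float | None = None
    natal_exit_method: str | None = None
    fw_exit_radius: float | None = None
    fw_exit_method: str | None = None
    natal_never_crossed: bool = False
    fw_never_crossed: bool = False


def _interp_crossing(r0, r1, y0, y1, threshold) -> float:
    if y1 == y0:
        return float(r0)
    return float(r0 + (threshold - y0) / (y1 - y0) * (r1 - r0))


def find_crossing(
    radius: np.ndarray,
    values: np.ndarray,
    threshold: float,
    direction: Direction,
    start_radius: float | None = None,
    min_run: int = 1,
) -> float | None:
    """Radius of the first threshold crossing in the stated direction.

    Returns the linearly interpolated radius of the first crossing at or
    after ``start_radius``, or ``None`` if the series never crosses.  A
    measurement exactly at the threshold counts as a crossing at its own
    radius.  With ``min_run > 1``, a crossing only qualifies if the next
    ``min_run`` measurements (starting at the segment end) all sit beyond
    the threshold.
    """
    radius = np.asarray(radius, dtype=float)
    values = np.asarray(values, dtype=float)
    if radius.size == 0:
        raise ValueError("empty profile")
    if np.any(np.diff(radius) <= 0):
        raise ValueError("radii must be strictly increasing")
    if direction not in ("downward", "upward"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = -1.0 if direction == "downward" else 1.0
    # work on sign-flipped values so a crossing is always "rises through threshold"
    v = sign * values
    thr = sign * threshold
    start = -np.inf if start_radius is None else float(start_radius)

    def run_ok(j: int) -> bool:
        # require min_run consecutive measurements at/beyond the threshold from j
        if min_run <= 1:
            return True
        if j + min_run > v.size:
            return False
        return bool(np.all(v[j : j + min_run] >= thr))

    n = v.size
    for i in range(n):
        # an exact-threshold measurement counts as a crossing at its own radius
        if v[i] == thr and radius[i] >= start and run_ok(i):
            return float(radius[i])
        if i + 1 < n and v[i] < thr < v[i + 1]:
            rc = _interp_crossing(
                radius[i], radius[i + 1], values[i], values[i + 1], threshold
            )
            if rc >= start and run_ok(i + 1):
                return rc
    return None


def normalize_srv(profile: ChemProfile, freshwater_only_max_radius: float | None = None) -> np.ndarray:
    """Min-max normalise the SrV series to [0, 1] over the whole transect.

    ``freshwater_only_max_radius`` restricts the scaling window (an
    alternative normalisation convention); the returned series still spans
    the full profile.  Raises on constant series, whose scaling is undefined.
    """
    if profile.srv is None or profile.srv.size < 2:
        raise ValueError("profile has no usable SrV series")
    window = profile.srv
    if freshwater_only_max_radius is not None:
        mask = profile.radius_um <= freshwater_only_max_radius
        if mask.sum() < 2:
            raise ValueError("freshwater-only window has <2 SrV measurements")
        window = profile.srv[mask]
    lo, hi = float(np.min(window)), float(np.max(window))
    if hi == lo:
        raise ValueError("constant SrV series: normalisation undefined")
    return (profile.srv - lo) / (hi - lo)


def natal_exit(
    profile: ChemProfile,
    iso: IsoscapeConfig,
    context: Context = "adult-or-bay",
    fw_exit_radius: float | None = None,
    min_run: int = 1,
) -> ExitEstimate:
    """Estimate the natal-exit radius (first downward crossing of the natal floor).

    Fallbacks when the profile never drops below ``ame_min_ratio``:

    * ``juvenile-above-chipps`` — the fish was still upstream of the estuary
      boundary when caught, so its total otolith radius is its natal-exit size.
    * ``adult-or-bay`` — the fish sprinted to sea; its freshwater-exit radius
      (which must already be resolved, e.g. via SrV) doubles as natal exit.
    * ``rst-measured`` — in-river trap fish use their measured FL directly;
      no profile inference happens here.
    """
    est = ExitEstimate(fish_id=profile.fish_id)
    if context == "rst-measured":
        est.natal_exit_method = "measured-FL"
        return est
    r = find_crossing(
        profile.radius_um, profile.sr_ratio, iso.ame_min_ratio, "downward", min_run=min_run
    )
    if r is not None:
        est.natal_exit_radius = r
        est.natal_exit_method = "ratio-crossing"
        return est
    est.natal_never_crossed = True
    if context == "juvenile-above-chipps":
        est.natal_exit_radius = float(profile.total_radius_um)
        est.natal_exit_method = "total-radius"
    elif context == "adult-or-bay":
        if fw_exit_radius is None:
            raise ValueError(
                "adult-or-bay natal fallback requires the freshwater exit radius "
                "to be resolved first"
            )
        est.natal_exit_radius = float(fw_exit_radius)
        est.natal_exit_method = "matched-to-freshwater-exit"
    else:
        raise ValueError(f"unknown context {context!r}")
    return est


def freshwater_exit(
    profile: ChemProfile,
    iso: IsoscapeConfig,
    natal_radius: float | None = None,
    srv_freshwater_only_max_radius: float | None = None,
    min_run: int = 1,
) -> ExitEstimate:
    """Estimate the freshwater-exit radius.

    Primary rule: first upward crossing of ``chipps_mean_ratio`` after
    ``natal_radius``.  Fallback: upward crossing of ``srv_exit_fraction`` in
    the min-max normalised SrV series (used for rapid migrants whose ratio
    profile never visits the Delta range).
    """
    est = ExitEstimate(fish_id=profile.fish_id)
    r = find_crossing(
        profile.radius_um,
        profile.sr_ratio,
        iso.chipps_mean_ratio,
        "upward",
        start_radius=natal_radius,
        min_run=min_run,
    )
    if r is not None:
        est.fw_exit_radius = r
        est.fw_exit_method = "ratio-crossing"
        return est
    est.fw_never_crossed = True
    if profile.srv is None:
        raise ValueError(
            f"fish {profile.fish_id}: ratio never crossed and no SrV series for fallback"
        )
    norm = normalize_srv(profile, srv_freshwater_only_max_radius)
    r = find_crossing(
        profile.radius_um, norm, iso.srv_exit_fraction, "upward", min_run=min_run
    )
    if r is None:
        raise ValueError(
            f"fish {profile.fish_id}: normalised SrV never crossed "
            f"{iso.srv_exit_fraction}"
        )
    est.fw_exit_radius = r
    est.fw_exit_method = "srv-crossing"
    return est


def reconstruct_exits(
    profile: ChemProfile,
    iso: IsoscapeConfig,
    context: Context = "adult-or-bay",
    min_run: int = 1,
) -> ExitEstimate:
    """Full per-fish reconstruction: natal then freshwater exit with fallbacks.

    For ``juvenile-above-chipps`` fish no freshwater exit is inferred (they
    had not left freshwater when caught).
    """
    natal = natal_exit(profile, iso, context="juvenile-above-chipps", min_run=min_run) \
        if context == "juvenile-above-chipps" else None

    if context == "juvenile-above-chipps":
        return natal

    fw = freshwater_exit(
        profile,
        iso,
        natal_radius=find_crossing(
            profile.radius_um, profile.sr_ratio, iso.ame_min_ratio, "downward", min_run=min_run
        ),
        min_run=min_run,
    )
    est = natal_exit(
        profile, iso, context=context, fw_exit_radius=fw.fw_exit_radius, min_run=min_run
    )
    est.fw_exit_radius = fw.fw_exit_radius
    est.fw_exit_method = fw.fw_exit_method
    est.fw_never_crossed = fw.fw_never_crossed
    if (
        est.natal_exit_radius is not None
        and est.fw_exit_radius is not None
        and est.natal_exit_radius > est.fw_exit_radius
    ):
        # interpolation jitter can put the natal crossing a hair past the
        # freshwater crossing for near-zero Delta residence; clamp.
        est.natal_exit_radius = est.fw_exit_radius
    return est


PROFILE_COLUMNS = ["fish_id", "radius_um", "sr8786", "sr8786_2se", "srv"]


def write_profiles_csv(profiles: Iterable[ChemProfile], path_or_buf: str | Path | IO) -> None:
    """Write profiles as tidy CSV, one row per measurement."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": p.fish_id,
                    "radius_um": p.radius_um,
                    "sr8786": p.sr_ratio,
                    "sr8786_2se": p.sr_ratio_2se
                    if p.sr_ratio_2se is not None
                    else np.nan,
                    "srv": p.srv if p.srv is not None else np.nan,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path_or_buf, index=False)


def read_profiles_csv(path_or_buf: str | Path | IO) -> list[ChemProfile]:
    """Read tidy profile CSV (columns fish_id, radius_um, sr8786, sr8786_2se, srv)."""
    df = pd.read_csv(path_or_buf)
    out = []
    for fish_id, grp in df.groupby("fish_id", sort=False):
        grp = grp.sort_values("radius_um")
        srv = grp["srv"].to_numpy() if "srv" in grp and grp["srv"].notna().all() else None
        se = (
            grp["sr8786_2se"].to_numpy()
            if "sr8786_2se" in grp and grp["sr8786_2se"].notna().all()
            else None
        )
        out.append(
            ChemProfile(
                fish_id=str(fish_id),
                radius_um=grp["radius_um"].to_numpy(),
                sr_ratio=grp["sr8786"].to_numpy(),
                sr_ratio_2se=se,
                srv=srv,
            )
        )
    return out
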