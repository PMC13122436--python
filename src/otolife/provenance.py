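"""Deterministic provenance rules layered over natal-assignment probabilities.

The upstream classifier (a random-forest model in the original workflow; a
simple stand-in for synthetic data, see :func:`standin_class_probabilities`)
supplies per-fish class probabilities over candidate sources.  This module
applies the deterministic screening and reassignment rules on top:

* :func:`lens_prescreen` — eye-lens natal δ³⁴S splits candidates into
  potentially wild (≤ 10.5‰), hatchery (marine-feed signal), and an
  estuarine-check bin (> 16‰, still analysed to rule out Bay rearing).
* :func:`juvenile_constraints` — juveniles < 55 mm FL are natural origin
  (hatcheries release no fry); fish sampled before a hatchery's first
  release that year cannot be from it; southern-tributary sources cannot
  appear at the upstream trawl.  Violated sources have their probability
  forced to zero and the fish is reassigned to the best remaining source.
* :func:`reassign_exogenous` — hatchery-assigned fish on the natal river
  (NIH) with weak assignment (p < 0.8) but a sharp exogenous feeding check
  (> 1.5) are reassigned to the wild natal source (AME).  The reverse
  reassignment is deliberately not applied.
* :func:`assign_age` — scale-read age when available, otherwise age 3
  with FL-based overrides (< 57 cm → 2, > 100 cm → 4).

Rule order for juveniles: constraints first, then the exogenous step.  Each
result carries the ordered list of rule IDs applied, for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssignmentInput",
    "ProvenanceResult",
    "lens_prescreen",
    "reassign_exogenous",
    "juvenile_constraints",
    "apply_juvenile_rules",
    "assign_age",
    "standin_class_probabilities",
]

LENS_WILD_MAX = 10.5  # ‰, inclusive
LENS_ESTUARINE_MIN = 16.0  # ‰, exclusive
FRY_MAX_FL = 55.0  # mm, strict
NIH_PROB_MAX = 0.8  # strict
EXO_MIN = 1.5  # strict

#: sources from southern tributaries that cannot occur at the upstream trawl
SOUTHERN_SOURCES = frozenset({"STN", "TUO", "MER"})
UPSTREAM_TRAWL_SITES = frozenset({"sherwood_harbor", "delta_entry"})


@dataclass
class AssignmentInput:
    """Candidate natal assignment plus the covariates the rules consult."""

    fish_id: str
    class_probabilities: dict[str, float]
    exo_score: float = 1.5
    lens_d34s: float | None = None
    fl_mm: float | None = None
    sample_month: int | None = None
    collection_site: str | None = None
    fin_clipped: bool = False

    @property
    def top_class(self) -> str:
        return max(self.class_probabilities, key=self.class_probabilities.get)

    def __post_init__(self) -> None:
        total = sum(self.class_probabilities.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class probabilities sum to {total}, not 1")
        if not 1.0 <= self.exo_score <= 2.0:
            raise ValueError("exo_score must lie in [1, 2]")


@dataclass
class ProvenanceResult:
    """Outcome of the rule cascade for one fish."""

    fish_id: str
    final_source: str | None
    class_probabilities: dict[str, float]
    applied_rules: list[str] = field(default_factory=list)
    prescreen: str | None = None
    unassignable: bool = False


def lens_prescreen(lens_d34s: float | None) -> str:
    """Classify the eye-lens natal δ³⁴S value.

    ≤ 10.5‰ → ``candidate-wild``; > 16‰ → ``estuarine-check`` (analysed
    anyway to rule out displaced early migrants rearing in brackish water);
    otherwise ``hatchery``.  Missing values (pre-lens-archive carcasses)
    pass through as ``no-lens``.
    """
    if lens_d34s is None or (isinstance(lens_d34s, float) and np.isnan(lens_d34s)):
        return "no-lens"
    if lens_d34s <= LENS_WILD_MAX:
        return "candidate-wild"
    if lens_d34s > LENS_ESTUARINE_MIN:
        return "estuarine-check"
    return "hatchery"


def reassign_exogenous(a: AssignmentInput) -> ProvenanceResult:
    """Reassign weakly NIH-assigned fish with sharp feeding checks to AME.

    Only fish whose top class is the on-river hatchery (NIH) with
    p(NIH) < 0.8 and exogenous score > 1.5 move; everything else is
    unchanged (the reverse AME→NIH rule is not applied).
    """
    res = ProvenanceResult(
        fish_id=a.fish_id,
        final_source=a.top_class,
        class_probabilities=dict(a.class_probabilities),
    )
    if (
        a.top_class == "NIH"
        and a.class_probabilities["NIH"] < NIH_PROB_MAX
        and a.exo_score > EXO_MIN
    ):
        res.final_source = "AME"
        res.applied_rules.append("exo-reassign-NIH-to-AME")
    return res


def _zero_and_renormalize(probs: dict[str, float], sources) -> dict[str, float]:
    out = dict(probs)
    for s in sources:
        if s in out:
            out[s] = 0.0
    total = sum(out.values())
    if total > 0:
        out = {k: v / total for k, v in out.items()}
    return out


def juvenile_constraints(
    a: AssignmentInput,
    hatchery_first_release_month: dict[str, int] | None = None,
    hatchery_sources: frozenset[str] | set[str] = frozenset({"NIH"}),
) -> ProvenanceResult:
    """Zero out sources a juvenile cannot have come from, then reassign.

    Constraints, each recorded as a rule ID when it fires: fry-size
    (< 55 mm FL excludes all hatchery sources), release-date (sampled
    before a hatchery's first unmarked release that year excludes it), and
    geography (southern tributaries excluded at the upstream trawl).
    Probabilities of excluded sources are forced to zero and renormalised;
    if everything is zeroed the fish is flagged unassignable.
    """
    probs = dict(a.class_probabilities)
    rules: list[str] = []
    if a.fl_mm is not None and a.fl_mm < FRY_MAX_FL:
        if any(probs.get(s, 0) > 0 for s in hatchery_sources):
            probs = _zero_and_renormalize(probs, hatchery_sources)
            rules.append("fry-size-natural-origin")
    if hatchery_first_release_month and a.sample_month is not None:
        late = [
            h
            for h, m in hatchery_first_release_month.items()
            if a.sample_month < m and probs.get(h, 0) > 0
        ]
        if late:
            probs = _zero_and_renormalize(probs, late)
            rules.append("before-first-hatchery-release")
    if a.collection_site in UPSTREAM_TRAWL_SITES:
        south = [s for s in SOUTHERN_SOURCES if probs.get(s, 0) > 0]
        if south:
            probs = _zero_and_renormalize(probs, south)
            rules.append("southern-source-at-upstream-trawl")

    total = sum(probs.values())
    if total == 0:
        return ProvenanceResult(
            fish_id=a.fish_id,
            final_source=None,
            class_probabilities=probs,
            applied_rules=rules,
            unassignable=True,
        )
    return ProvenanceResult(
        fish_id=a.fish_id,
        final_source=max(probs, key=probs.get),
        class_probabilities=probs,
        applied_rules=rules,
    )


def apply_juvenile_rules(
    a: AssignmentInput,
    hatchery_first_release_month: dict[str, int] | None = None,
) -> ProvenanceResult:
    """Full juvenile cascade: constraints first, then the exogenous step."""
    res = juvenile_constraints(a, hatchery_first_release_month)
    if res.unassignable:
        return res
    a2 = AssignmentInput(
        fish_id=a.fish_id,
        class_probabilities=res.class_probabilities,
        exo_score=a.exo_score,
        lens_d34s=a.lens_d34s,
        fl_mm=a.fl_mm,
        sample_month=a.sample_month,
        collection_site=a.collection_site,
    )
    res2 = reassign_exogenous(a2)
    res2.applied_rules = res.applied_rules + res2.applied_rules
    return res2


def assign_age(scale_age: int | float | None, fl_cm: float) -> int:
    """Return age: scale read when available, else 3 with FL overrides."""
    if scale_age is not None and not (isinstance(scale_age, float) and np.isnan(scale_age)):
        return int(scale_age)
    if fl_cm < 57.0:
        return 2
    if fl_cm > 100.0:
        return 4
    return 3


def standin_class_probabilities(
    profile,
    reference_ratios: dict[str, float],
    window_um: tuple[float, float] = (100.0, 250.0),
    scale: float = 2e-4,
) -> dict[str, float]:
    """Stand-in natal classifier for synthetic data.

    Softmax over candidate sources of minus the distance between the mean
    early-transect ⁸⁷Sr/⁸⁶Sr and each source's reference water value.  The
    default window's upper bound sits below the smallest back-calculable
    natal-exit radius (256 μm, the regression branch joint), so for every
    fish — including the earliest migrants, whose profiles drop toward the
    Delta value soon after — the window reflects natal water only.  This is
    deliberately simple: the full random-forest assignment model is an
    upstream input in real use, and this stand-in only supplies plausible
    probabilities to exercise the rule layer on simulated fish.
    """
    mask = (profile.radius_um >= window_um[0]) & (profile.radius_um <= window_um[1])
    if not mask.any():
        mask = profile.radius_um <= profile.radius_um[0] + (window_um[1] - window_um[0])
    mean_ratio = float(profile.sr_ratio[mask].mean())
    logits = {s: -abs(mean_ratio - r) / scale for s, r in reference_ratios.items()}
    m = max(logits.values())
    exps = {s: np.exp(v - m) for s, v in logits.items()}
    total = sum(exps.values())
    return {s: float(v / total) for s, v in exps.items()}
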