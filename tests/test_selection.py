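"""Selection differentials, their regressions, and catch expansion."""

import numpy as np
import pandas as pd
import pytest

from otolife.config import IsoscapeConfig, SimConfig
from otolife.selection import (
    expand_to_catch,
    regress_i,
    segment_differentials,
    selection_differential,
)
from otolife.simulate import simulate_cohort


def test_identical_samples_give_zero():
    x = np.array([40.0, 50.0, 60.0, 55.0])
    assert selection_differential(x, x).i == pytest.approx(0.0, abs=1e-12)


def test_variance_denominator_arithmetic():
    """Direct arithmetic under the variance convention: Δ=10, v=100 → 0.1."""
    rng = np.random.default_rng(0)
    init = rng.normal(50, 10, 20000)
    surv = init + 10.0
    res = selection_differential(init, surv, standardize_by="variance")
    assert res.i == pytest.approx(10.0 / res.v_init, abs=1e-12)
    assert res.i == pytest.approx(0.1, abs=0.01)
    # under the default SD convention the same shift is ≈ 1 SD
    res_sd = selection_differential(init, surv)
    assert res_sd.i == pytest.approx(1.0, abs=0.05)


def test_truncation_selection_matches_explicit_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(100):
        init = rng.normal(rng.uniform(40, 60), rng.uniform(5, 15), rng.integers(20, 200))
        surv = init[init >= np.median(init)]
        for mode in ("sd", "variance"):
            res = selection_differential(init, surv, standardize_by=mode)
            denom = np.std(init, ddof=1) if mode == "sd" else np.var(init, ddof=1)
            want = (surv.mean() - init.mean()) / denom
            assert res.i == pytest.approx(want, abs=1e-12)
        assert res.i > 0  # survivors larger ⇒ positive selection


def test_location_and_scale_behaviour():
    rng = np.random.default_rng(2)
    init = rng.normal(50, 10, 500)
    surv = init[init > 45]
    base_sd = selection_differential(init, surv).i
    base_var = selection_differential(init, surv, standardize_by="variance").i
    shift = selection_differential(init + 7, surv + 7)
    assert shift.i == pytest.approx(base_sd, abs=1e-12)
    # multiplying both samples by c: SD-standardised i is invariant,
    # variance-standardised i scales as 1/c
    c = 3.0
    assert selection_differential(c * init, c * surv).i == pytest.approx(base_sd, abs=1e-12)
    assert selection_differential(
        c * init, c * surv, standardize_by="variance"
    ).i == pytest.approx(base_var / c, abs=1e-12)


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        selection_differential([50.0], [50.0])
    with pytest.raises(ValueError):
        selection_differential([50.0, 50.0], [50.0])


def test_segment_differentials_equal_pairwise_oracle():
    rng = np.random.default_rng(3)
    rows = []
    for year in (2014, 2015):
        for point, mu in (("delta_entry", 45), ("delta_exit", 55), ("spawning", 65)):
            for v in rng.normal(mu, 10, 50):
                rows.append(
                    {"collection_point": point, "outmigration_year": year, "natal_exit_fl": v}
                )
    rec = pd.DataFrame(rows)
    out = segment_differentials(rec)
    assert len(out) == 6
    for _, r in out.iterrows():
        p0, p1 = {
            "Delta": ("delta_entry", "delta_exit"),
            "Ocean": ("delta_exit", "spawning"),
            "All": ("delta_entry", "spawning"),
        }[r.segment]
        grp = rec[rec.outmigration_year == r.year]
        want = selection_differential(
            grp.loc[grp.collection_point == p0, "natal_exit_fl"],
            grp.loc[grp.collection_point == p1, "natal_exit_fl"],
        )
        assert r.i == pytest.approx(want.i, abs=1e-12)


def test_missing_segment_endpoint_skipped():
    rng = np.random.default_rng(4)
    rec = pd.DataFrame(
        {
            "collection_point": ["delta_entry"] * 30 + ["delta_exit"] * 30,
            "outmigration_year": [2014] * 60,
            "natal_exit_fl": rng.normal(50, 10, 60),
        }
    )
    out = segment_differentials(rec)
    assert set(out.segment) == {"Delta"}


def test_estimated_i_increases_with_selection_slope(iso):
    """Monotone response of the estimated Delta differential to the
    generator's logistic survival slope (census-level, 20 seed-slope pairs)."""
    slopes = np.linspace(0.0, 0.12, 20)
    i_vals = []
    for k, slope in enumerate(slopes):
        cfg = SimConfig(
            n_fish=2500,
            hatchery_fraction=0.0,
            delta_selection_slope=float(slope),
            delta_base_survival=0.4,
            seed=100 + k,
        )
        hs, _, _ = simulate_cohort(cfg, iso, rng=np.random.default_rng(100 + k))
        init = [h.natal_exit_fl_true for h in hs]
        surv = [h.natal_exit_fl_true for h in hs if h.survived_to != "delta_entry"]
        i_vals.append(selection_differential(init, surv).i)
    # strong positive rank correlation, start near zero, end clearly positive
    assert np.corrcoef(slopes, i_vals)[0, 1] > 0.9
    assert abs(i_vals[0]) < 0.15
    assert i_vals[-1] > 0.5


def test_sampling_estimate_matches_census_within_mc_error(iso):
    """Differential from finite catches is an unbiased image of the census
    differential (200 resampled catches, ±3 SE)."""
    cfg = SimConfig(n_fish=4000, hatchery_fraction=0.0, seed=5)
    hs, _, _ = simulate_cohort(cfg, iso, rng=np.random.default_rng(5))
    init = np.array([h.natal_exit_fl_true for h in hs])
    surv = np.array([h.natal_exit_fl_true for h in hs if h.survived_to != "delta_entry"])
    census = selection_differential(init, surv).i
    rng = np.random.default_rng(6)
    draws = [
        selection_differential(
            rng.choice(init, 100, replace=False), rng.choice(surv, 60, replace=False)
        ).i
        for _ in range(200)
    ]
    se = np.std(draws, ddof=1) / np.sqrt(len(draws))
    assert abs(np.mean(draws) - census) < 3 * se + 0.02


class TestRegressions:
    def test_quadratic_recovery(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 10, 40)
        y = 2.0 + 1.5 * x - 0.3 * x**2 + rng.normal(0, 0.1, x.size)
        fit = regress_i(y, x, form="quadratic")
        for got, want in zip(fit.params, (2.0, 1.5, -0.3)):
            assert got == pytest.approx(want, abs=0.15)

    def test_constant_response_nonsignificant(self):
        x = np.linspace(0, 10, 20)
        y = np.full_like(x, 3.0) + np.random.default_rng(8).normal(0, 1e-6, x.size)
        fit = regress_i(y, x, form="linear")
        assert abs(fit.params[1]) < 1e-4

    def test_linear_data_has_negligible_quadratic_term(self):
        x = np.linspace(1, 10, 25)
        y = 1.0 + 2.0 * x
        fit = regress_i(y, x, form="quadratic")
        assert fit.params[2] == pytest.approx(0.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            regress_i([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], form="quadratic")


class TestExpandToCatch:
    def _sample(self, rng, months, n_per):
        rows = []
        for m in months:
            for v in rng.normal(40 + 5 * m, 3, n_per):
                rows.append({"sample_month": m, "fl": v})
        return pd.DataFrame(rows)

    def test_proportional_catch_preserves_distribution(self):
        rng = np.random.default_rng(9)
        df = self._sample(rng, [1, 2, 3], 50)
        catch = {1: 500, 2: 500, 3: 500}
        out = expand_to_catch(df, catch, bin_months=1, seed=9)
        assert len(out) == 1500
        assert abs(out.fl.mean() - df.fl.mean()) < 1.0

    def test_all_catch_in_one_bin(self):
        rng = np.random.default_rng(10)
        df = self._sample(rng, [1, 2], 30)
        out = expand_to_catch(df, {1: 400, 2: 0}, bin_months=1, seed=10)
        assert (out.sample_month == 1).all()

    def test_two_bin_catch_ratio_expectation(self):
        """3:1 catch ratio → expected bin shares 0.75/0.25."""
        rng = np.random.default_rng(11)
        df = self._sample(rng, [1, 2], 40)
        shares = []
        for s in range(300):
            out = expand_to_catch(df, {1: 30, 2: 10}, bin_months=1, seed=s, total=40)
            shares.append((out.sample_month == 1).mean())
        assert np.mean(shares) == pytest.approx(0.75, abs=0.02)

    def test_empty_bin_merged_forward(self):
        rng = np.random.default_rng(12)
        df = self._sample(rng, [2, 3], 30)  # no samples in month 1
        out = expand_to_catch(df, {1: 100, 2: 100, 3: 100}, bin_months=1, seed=12)
        assert len(out) == 300
        # month-1 catch reassigned to the month-2 sample pool
        assert (out.sample_month == 2).sum() > (out.sample_month == 3).sum()
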