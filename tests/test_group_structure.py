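import numpy as np
import pandas as pd
import pytest

from trackways.data import TrackwaySummary
from trackways.group_structure import (
    CATEGORIES,
    AgeSexCutoffs,
    GroupStructureResult,
    ResamplingConfig,
    classify_age_sex,
    estimate_age_cutoffs,
    largest_track_cutoff,
    proportional_windows,
    run_resampling,
    summarize_group_structure,
    uniform_age_downsample,
)
from trackways.synthetic import (
    GrowthCurve,
    PopulationGenConfig,
    generate_anthropometric_population,
)


def _pop(rows):
    return pd.DataFrame(
        [dict(person_id=f"p{i}", sex=s, age_yr=a, foot_length_mm=f)
         for i, (s, a, f) in enumerate(rows)]
    )


def _summ(tid, med):
    return TrackwaySummary(tid, med)


class TestAgeCutoffs:
    def test_fixed_returns_published_cessation_ages(self):
        c = estimate_age_cutoffs(pd.DataFrame(), method="fixed")
        assert (c.female_adult_age_yr, c.male_adult_age_yr) == (14.0, 17.8)

    def test_breakpoint_recovers_true_plateau(self):
        cfg = PopulationGenConfig(
            n_male=750, n_female=750,
            growth={
                "female": GrowthCurve(130.0, 15.0, 230.0, noise_sd_mm=5.0),
                "male": GrowthCurve(135.0, 15.0, 250.0, noise_sd_mm=5.0),
            },
            seed=11,
        )
        pop, _ = generate_anthropometric_population(cfg)
        c = estimate_age_cutoffs(pop, method="breakpoint")
        assert abs(c.female_adult_age_yr - 15.0) < 1.0
        assert abs(c.male_adult_age_yr - 15.0) < 1.0

    def test_linear_growth_flagged_at_boundary(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(2, 30, 300)
        rows = [("female", a, 100 + 5 * a + rng.normal(0, 2)) for a in age]
        rows += [("male", a, 100 + 5 * a + rng.normal(0, 2)) for a in age]
        c = estimate_age_cutoffs(_pop(rows), method="breakpoint")
        assert any(c.diagnostics.values())

    def test_no_juveniles_errors(self):
        rows = [("female", 30.0, 230.0)] * 20 + [("male", 30.0, 250.0)] * 20
        with pytest.raises(ValueError, match="juvenile"):
            estimate_age_cutoffs(_pop(rows), method="breakpoint")


class TestDownsample:
    def test_oversized_bin_capped(self):
        rows = [("female", 19.0, 220.0)] * 120
        out = uniform_age_downsample(_pop(rows), ResamplingConfig(), np.random.default_rng(0))
        assert len(out) == 50

    def test_small_bin_untouched(self):
        rows = [("male", 5.0, 170.0)] * 30
        out = uniform_age_downsample(_pop(rows), ResamplingConfig(), np.random.default_rng(0))
        assert len(out) == 30

    def test_conservation(self, population):
        records, _ = population
        cfg = ResamplingConfig()
        out = uniform_age_downsample(records, cfg, np.random.default_rng(1))
        assert len(out) <= len(records)
        # equality iff no sex x 2-yr bin exceeds the cap
        bins = (records["age_yr"] // cfg.bin_width_yr).astype(int)
        max_bin = records.groupby([records["sex"], bins]).size().max()
        assert (len(out) == len(records)) == (max_bin <= cfg.bin_cap)
        # no bin exceeds the cap afterwards
        obins = (out["age_yr"] // cfg.bin_width_yr).astype(int)
        assert out.groupby([out["sex"], obins]).size().max() <= cfg.bin_cap


class TestLargestCutoff:
    def test_hand_arithmetic(self):
        rows = [("male", 30.0, f) for f in (260.0, 270.0, 280.0)]
        pop = _pop(rows + [("female", 30.0, 230.0)] * 2)
        assert largest_track_cutoff(pop, AgeSexCutoffs(), 1.0) == pytest.approx(280.0)
        assert largest_track_cutoff(pop, AgeSexCutoffs(), 0.0) == pytest.approx(270.0)

    def test_needs_two_adult_males(self):
        pop = _pop([("male", 30.0, 260.0), ("male", 5.0, 170.0), ("female", 30.0, 230.0)])
        with pytest.raises(ValueError, match="adult males"):
            largest_track_cutoff(pop, AgeSexCutoffs())

    def test_normal_tail_share(self, population):
        """On the generated population, the cutoff exceeds the adult-male
        mean and leaves roughly the expected one-sided normal tail (~16%)
        of adult males eligible."""
        records, _ = population
        cut = largest_track_cutoff(records, AgeSexCutoffs(), 1.0)
        cats = classify_age_sex(records, AgeSexCutoffs())
        feet = records.loc[cats == "AM", "foot_length_mm"]
        assert cut > feet.mean()
        share = float((feet >= cut).mean())
        assert 0.10 <= share <= 0.22


class TestProportionalWindows:
    def test_largest_gets_unit_proportion(self):
        w = proportional_windows([_summ("big", 289.5), _summ("small", 217.125)])
        big = w[w["is_largest"]].iloc[0]
        assert big["trackway_id"] == "big"
        assert big["proportion"] == pytest.approx(1.0)
        assert (big["low_frac"], big["high_frac"]) == (pytest.approx(0.95), pytest.approx(1.05))

    def test_hand_arithmetic(self):
        w = proportional_windows([_summ("big", 289.5), _summ("small", 217.125)])
        small = w[~w["is_largest"]].iloc[0]
        assert small["proportion"] == pytest.approx(0.75)
        assert small["low_frac"] == pytest.approx(0.7125)
        assert small["high_frac"] == pytest.approx(0.7875)

    def test_equal_medians_identical_windows(self):
        w = proportional_windows([_summ("a", 250.0), _summ("b", 250.0)])
        assert w["low_frac"].nunique() == 1 and w["high_frac"].nunique() == 1
        # tie broken lexicographically
        assert w.loc[w["is_largest"], "trackway_id"].item() == "a"


def _enumeration_oracle(records, summaries, cutoffs, cfg):
    """Exact per-trackway category probabilities for populations in which
    no age bin exceeds the cap: enumerate eligible largest feet (uniform),
    then each trackway's eligible-set category shares, averaged."""
    windows = proportional_windows(summaries, cfg.window_low, cfg.window_high)
    cut = largest_track_cutoff(records, cutoffs, cfg.largest_cutoff_sd)
    feet = records["foot_length_mm"].to_numpy(float)
    cats = classify_age_sex(records, cutoffs).map(
        {c: i for i, c in enumerate(CATEGORIES)}
    ).to_numpy()
    eligible_big = np.flatnonzero(feet >= cut)
    probs = {tid: np.zeros(4) for tid in windows["trackway_id"]}
    for big in eligible_big:
        ok = True
        shares = {}
        for row in windows.itertuples(index=False):
            if row.is_largest:
                shares[row.trackway_id] = np.eye(4)[cats[big]]
                continue
            mask = (feet >= row.low_frac * feet[big]) & (feet <= row.high_frac * feet[big])
            if not mask.any():
                ok = False
                break
            shares[row.trackway_id] = np.bincount(cats[mask], minlength=4) / mask.sum()
        assert ok, "oracle population must leave no window empty"
        for tid, s in shares.items():
            probs[tid] += s / len(eligible_big)
    return probs


class TestRunResampling:
    def test_disjoint_size_classes_certain_attribution(self):
        """Three trackways whose sizes isolate adult-male, adult-female and
        juvenile feet are attributed with probability 1."""
        rows = (
            [("male", 30.0, f) for f in (280.0, 285.0, 290.0, 295.0, 300.0)]
            + [("female", 30.0, f) for f in (230.0, 232.5, 235.0, 237.5, 240.0)]
            + [("male", 8.0, f) for f in (170.0, 172.5, 175.0, 177.5, 180.0)]
        )
        pop = _pop(rows)
        summaries = [_summ("am", 290.0), _summ("af", 235.0), _summ("juv", 175.0)]
        res = run_resampling(pop, summaries, AgeSexCutoffs(),
                             ResamplingConfig(n_iterations=400, seed=0))
        attr = res.attribution_probabilities().set_index("trackway_id")
        assert attr.loc["am", "p_am"] == 1.0
        assert attr.loc["af", "p_af"] == 1.0
        assert attr.loc["juv", "p_jm"] + attr.loc["juv", "p_jf"] == 1.0

    def test_matches_enumeration_oracle(self):
        """Monte-Carlo attribution probabilities agree with the exact
        enumeration over eligible feet within 3 MC standard errors."""
        rng = np.random.default_rng(5)
        rows = (
            [("male", 30.0, f) for f in rng.normal(265, 12, 20)]
            + [("female", 30.0, f) for f in rng.normal(230, 12, 20)]
            + [("male", 9.0, f) for f in rng.normal(195, 15, 8)]
            + [("female", 9.0, f) for f in rng.normal(190, 15, 8)]
        )
        pop = _pop(rows)
        summaries = [_summ("t1", 280.0), _summ("t2", 235.0), _summ("t3", 205.0)]
        cfg = ResamplingConfig(n_iterations=10_000, seed=42)
        exact = _enumeration_oracle(pop, summaries, AgeSexCutoffs(), cfg)
        res = run_resampling(pop, summaries, AgeSexCutoffs(), cfg)
        attr = res.attribution_probabilities().set_index("trackway_id")
        B = cfg.n_iterations
        for tid, p_exact in exact.items():
            p_hat = attr.loc[tid, [f"p_{c.lower()}" for c in CATEGORIES]].to_numpy(float)
            for pe, ph in zip(p_exact, p_hat):
                if pe in (0.0, 1.0):
                    assert ph == pe
                else:
                    se = np.sqrt(pe * (1 - pe) / B)
                    assert abs(ph - pe) <= 3 * se

    def test_window_monotonicity(self):
        """Widening the size window never shrinks any trackway's eligible
        comparative set, for every possible largest-foot draw."""
        rng = np.random.default_rng(7)
        feet = np.concatenate([rng.normal(260, 15, 30), rng.normal(200, 20, 20)])
        summaries = [_summ("a", 280.0), _summ("b", 240.0), _summ("c", 200.0)]
        narrow = proportional_windows(summaries, 0.95, 1.05)
        wide = proportional_windows(summaries, 0.90, 1.10)
        for big in feet[feet >= np.quantile(feet, 0.8)]:
            for wn, ww in zip(narrow.itertuples(), wide.itertuples()):
                n_narrow = np.sum((feet >= wn.low_frac * big) & (feet <= wn.high_frac * big))
                n_wide = np.sum((feet >= ww.low_frac * big) & (feet <= ww.high_frac * big))
                assert n_wide >= n_narrow

    def test_constraints_hold_every_iteration(self, population, engare_sero):
        records, _ = population
        _, summaries, _ = engare_sero
        cfg = ResamplingConfig(n_iterations=300, seed=8)
        res = run_resampling(records, summaries, AgeSexCutoffs(), cfg)
        # proportions sum to one in every iteration
        np.testing.assert_allclose(res.proportions.sum(axis=1), 1.0, atol=1e-12)
        # every drawn foot lies inside its trackway's window
        windows = proportional_windows(summaries, cfg.window_low, cfg.window_high)
        largest_pos = int(np.flatnonzero(windows["is_largest"])[0])
        big = res.foot_draws[largest_pos]
        assert np.all(big >= res.largest_cutoff_mm)
        low = windows["low_frac"].to_numpy()[:, None]
        high = windows["high_frac"].to_numpy()[:, None]
        inside = (res.foot_draws >= low * big - 1e-9) & (res.foot_draws <= high * big + 1e-9)
        inside[largest_pos] = True
        assert inside.all()

    def test_bit_reproducible(self, population, engare_sero):
        records, _ = population
        _, summaries, _ = engare_sero
        cfg = ResamplingConfig(n_iterations=150, seed=13)
        a = run_resampling(records, summaries, AgeSexCutoffs(), cfg)
        b = run_resampling(records, summaries, AgeSexCutoffs(), cfg)
        assert np.array_equal(a.category_draws, b.category_draws)
        assert np.array_equal(a.foot_draws, b.foot_draws)

    def test_unreachable_largest_cutoff_errors(self):
        rows = [("male", 30.0, 250.0), ("male", 30.0, 251.0), ("female", 30.0, 230.0)]
        pop = _pop(rows)
        # cutoff = mean + 20 sd: nothing qualifies
        cfg = ResamplingConfig(n_iterations=5, seed=0, largest_cutoff_sd=20.0)
        with pytest.raises(ValueError, match="cutoff"):
            run_resampling(pop, [_summ("a", 280.0)], AgeSexCutoffs(), cfg)


def _manual_result(**overrides):
    n = 3
    base = dict(
        trackway_ids=["a"],
        category_draws=np.zeros((1, n), dtype=np.int8),
        foot_draws=np.full((1, n), 250.0),
        proportions=np.tile([1.0, 0.0, 0.0, 0.0], (n, 1)),
        adult_sex_ratio=np.array([1.0, 2.0, 3.0]),
        log_sex_ratio=np.log([1.0, 2.0, 3.0]),
        adult_juvenile_ratio=np.array([1.0, 2.0, 3.0]),
        log_dimorphism=np.zeros(n),
        largest_cutoff_mm=260.0,
        config=ResamplingConfig(n_iterations=n),
        n_redrawn_iterations=0,
    )
    base.update(overrides)
    return GroupStructureResult(**base)


class TestSummarize:
    def test_identical_iterations_zero_width_cis(self):
        r = _manual_result(adult_sex_ratio=np.full(3, 0.5),
                           adult_juvenile_ratio=np.full(3, 2.0))
        summary, _ = summarize_group_structure(r)
        s = summary.set_index("quantity")
        row = s.loc["adult sex ratio"]
        assert row["median"] == row["ci_low"] == row["ci_high"] == 0.5

    def test_ratio_median(self):
        summary, _ = summarize_group_structure(_manual_result())
        s = summary.set_index("quantity")
        assert s.loc["adult to juvenile ratio", "median"] == 2.0

    def test_equal_sex_means_zero_log_dimorphism(self):
        summary, _ = summarize_group_structure(_manual_result())
        s = summary.set_index("quantity")
        assert s.loc["log adult foot length dimorphism", "median"] == 0.0

    def test_undefined_ratios_excluded_and_counted(self):
        r = _manual_result(adult_juvenile_ratio=np.array([np.nan, 2.0, 4.0]))
        summary, _ = summarize_group_structure(r)
        s = summary.set_index("quantity")
        assert s.loc["adult to juvenile ratio", "n_excluded_iterations"] == 1
        assert s.loc["adult to juvenile ratio", "median"] == 3.0

    def test_attribution_tie_flagged_fixed_order(self):
        draws = np.array([[0, 1, 0, 1]], dtype=np.int8)  # 2 AM, 2 AF
        r = _manual_result(
            category_draws=draws, foot_draws=np.full((1, 4), 250.0),
            proportions=np.tile([0.5, 0.5, 0, 0], (4, 1)),
            adult_sex_ratio=np.ones(4), log_sex_ratio=np.zeros(4),
            adult_juvenile_ratio=np.full(4, np.nan), log_dimorphism=np.zeros(4),
            config=ResamplingConfig(n_iterations=4),
        )
        attr = r.attribution_probabilities()
        assert attr.loc[0, "most_probable"] == "AM"  # first in fixed order
        assert bool(attr.loc[0, "tie"])
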