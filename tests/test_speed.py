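import numpy as np
import pandas as pd
import pytest

from trackways.data import TrackwaySummary
from trackways.speed import (
    GaitClassifier,
    classify_gait,
    fit_gait_classifier,
    fit_velocity_model,
    predict_assemblage,
    predict_velocity,
)
from trackways.synthetic import (
    AssemblageGenConfig,
    ExperimentGenConfig,
    generate_experimental_dataset,
    generate_fossil_assemblage,
)
from trackways.data import summarize_trackway


def _trials(rsl_walk, rsl_run, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, r in enumerate(rsl_walk):
        rows.append(dict(subject_id=f"s{i % 8}", gait="walk", rsl=r,
                         velocity_mps=0.3 * r + rng.normal(0, 0.01)))
    for i, r in enumerate(rsl_run):
        rows.append(dict(subject_id=f"s{i % 8}", gait="run", rsl=r,
                         velocity_mps=0.5 * r + rng.normal(0, 0.01)))
    return pd.DataFrame(rows)


class TestGaitClassifier:
    def test_separable_data_perfect_auc(self):
        rng = np.random.default_rng(1)
        walk = rng.normal(5.5, 0.3, 60)
        run = rng.normal(8.0, 0.5, 60)
        assert walk.max() < run.min()
        c = fit_gait_classifier(_trials(walk, run))
        assert c.auc == pytest.approx(1.0)
        assert walk.max() < c.rsl_threshold <= run.min() + 1e-9

    def test_no_signal_auc_half(self):
        c = fit_gait_classifier(_trials([6.0] * 30, [6.0] * 30))
        assert c.auc == pytest.approx(0.5, abs=0.01)

    def test_single_gait_errors(self):
        with pytest.raises(ValueError, match="cannot fit classifier"):
            fit_gait_classifier(_trials([5.0, 5.5, 6.0], []))

    def test_probability_monotone_in_rsl(self, experiment):
        _, trials = experiment
        c = fit_gait_classifier(trials)
        grid = np.linspace(3, 12, 50)
        p = c.run_probability(grid)
        assert np.all(np.diff(p) >= 0)

    def test_fixture_rsl_classifications(self, experiment):
        """Trained on the default generator, RSL 5.00 walks and 8.58 runs."""
        _, trials = experiment
        c = fit_gait_classifier(trials)
        assert classify_gait(c, 5.00) == "walk"
        assert classify_gait(c, 8.58) == "run"

    def test_tie_classifies_as_run(self):
        c = GaitClassifier(intercept=-8.0, slope=1.0, decision_threshold=0.5,
                           rsl_threshold=8.0, auc=1.0, confusion={})
        assert classify_gait(c, 8.0) == "run"  # P(run) exactly 0.5

    def test_nonpositive_rsl_rejected(self, experiment):
        _, trials = experiment
        c = fit_gait_classifier(trials)
        with pytest.raises(ValueError):
            classify_gait(c, 0.0)

    def test_refit_is_deterministic(self, experiment):
        _, trials = experiment
        a = fit_gait_classifier(trials, seed=3)
        b = fit_gait_classifier(trials, seed=3)
        assert a.intercept == b.intercept and a.slope == b.slope
        assert a.decision_threshold == b.decision_threshold


class TestVelocityModel:
    def test_noiseless_exact_recovery(self):
        rsl = np.linspace(4, 7, 24)
        df = pd.DataFrame(dict(
            subject_id=[f"s{i % 6}" for i in range(24)], gait="walk",
            rsl=rsl, velocity_mps=0.25 * rsl + 0.05,
        ))
        m = fit_velocity_model(df, "walk")
        assert m.slope == pytest.approx(0.25, abs=1e-6)
        assert m.intercept == pytest.approx(0.05, abs=1e-6)
        assert m.rmse_mps == pytest.approx(0.0, abs=1e-9)

    def test_constant_rsl_errors(self):
        df = pd.DataFrame(dict(subject_id=["a", "b"] * 4, gait="walk",
                               rsl=[5.0] * 8, velocity_mps=np.arange(8.0) + 1))
        with pytest.raises(ValueError, match="degenerate"):
            fit_velocity_model(df, "walk")

    def test_needs_two_subjects(self):
        df = pd.DataFrame(dict(subject_id="only", gait="walk",
                               rsl=[5.0, 6.0], velocity_mps=[1.2, 1.5]))
        with pytest.raises(ValueError, match="subjects"):
            fit_velocity_model(df, "walk")

    def test_slope_recovered_within_2se(self):
        """With footprint elongation off, the mixed model recovers the
        generating walk slope within 2 standard errors."""
        cfg = ExperimentGenConfig(
            seed=5, elongation_base=0.0, elongation_slope_per_mps=0.0,
            elongation_sd=0.0, n_excluded_trials=0,
        )
        gen = generate_experimental_dataset(cfg)
        m = fit_velocity_model(gen.trials, "walk")
        true_slope = cfg.velocity_on_rsl["walk"][1]
        assert abs(m.slope - true_slope) < 2 * m.slope_se

    def test_prediction_monotone_in_rsl(self, experiment):
        _, trials = experiment
        m = fit_velocity_model(trials, "walk")
        assert m.slope > 0
        assert float(m.predict(5.69)) > float(m.predict(5.00))

    def test_heldout_rmse_near_generator_noise(self):
        """RMSE on held-out subjects stays within 25% of the generator's
        prediction-noise floor.  The floor combines the subject and
        residual velocity sds with the velocity-scale noise induced by
        footprint elongation on the measured RSL (slope x mean RSL x
        elongation sd) — all known to the generator."""
        cfg = ExperimentGenConfig(seed=9, n_excluded_trials=0)
        gen = generate_experimental_dataset(cfg)
        trials = gen.trials
        subjects = sorted(trials["subject_id"].unique())
        train = trials[trials["subject_id"].isin(subjects[:31])]
        test = trials[trials["subject_id"].isin(subjects[31:])]
        m = fit_velocity_model(train, "walk")
        tw = test[test["gait"] == "walk"]
        rsl = (tw["stride_length_mm"] / tw["footprint_length_mm"]).to_numpy()
        rmse = float(np.sqrt(np.mean((tw["velocity_mps"].to_numpy() - m.predict(rsl)) ** 2)))
        mean_walk_rsl = np.mean([cfg.category_rsl[c][0] for c in ("normal walk", "fast walk")])
        slope = cfg.velocity_on_rsl["walk"][1]
        floor = np.sqrt(
            cfg.subject_velocity_sd**2
            + cfg.residual_velocity_sd**2
            + (slope * mean_walk_rsl * cfg.elongation_sd) ** 2
        )
        assert abs(rmse - floor) / floor < 0.25


class TestPredictVelocity:
    @pytest.fixture(scope="class")
    def models(self, experiment):
        _, trials = experiment
        return (
            fit_gait_classifier(trials),
            fit_velocity_model(trials, "walk"),
            fit_velocity_model(trials, "run"),
        )

    def test_missing_rsl_errors(self, models):
        s = TrackwaySummary("q", 250.0, relative_stride_length=None)
        with pytest.raises(ValueError, match="stride length required"):
            predict_velocity(s, *models)

    def test_extrapolation_flag_below_training_range(self, models):
        s = TrackwaySummary("q", 250.0, relative_stride_length=2.0)
        p = predict_velocity(s, *models)
        assert p.extrapolated

    def test_band_is_symmetric_rmse(self, models):
        s = TrackwaySummary("q", 250.0, relative_stride_length=5.5)
        p = predict_velocity(s, *models)
        assert p.band_high_mps - p.velocity_mps == pytest.approx(
            p.velocity_mps - p.band_low_mps
        )

    def test_fixture_has_exactly_one_runner(self, models, engare_sero):
        _, summaries, _ = engare_sero
        table = predict_assemblage(summaries, *models)
        assert len(table) == 23
        assert (table["gait"] == "run").sum() == 1
        assert table.loc[table["gait"] == "run", "trackway_id"].item() == "B"

    def test_synthetic_assemblage_speed_recovery(self, models):
        """Known-speed synthetic trackways are recovered with mean absolute
        error below 1.5x the training RMSE."""
        classifier, walk_model, run_model = models
        asm = generate_fossil_assemblage(AssemblageGenConfig(seed=21))
        summaries = [summarize_trackway(t) for t in asm.trackways]
        table = predict_assemblage(summaries, classifier, walk_model, run_model)
        merged = table.merge(
            asm.truth, left_on="trackway_id", right_on="trackway_id"
        )
        mae = float((merged["velocity_mps_x"] - merged["velocity_mps_y"]).abs().mean())
        assert mae < 1.5 * walk_model.rmse_mps
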