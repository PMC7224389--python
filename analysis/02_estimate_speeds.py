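"""Estimate travel speeds for the bundled trackway assemblage.

Fits the logistic walk/run classifier and the gait-specific mixed
velocity models on the synthetic experimental trials, then predicts
gait and velocity for every trackway with measured strides.  Writes
results/speed_table.csv (the per-trackway speed table layout).
"""

from pathlib import Path

import pandas as pd

from trackways.fixtures import engare_sero_fixture
from trackways.speed import fit_gait_classifier, fit_velocity_model, predict_assemblage
from trackways.synthetic import ExperimentGenConfig, generate_experimental_dataset

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gen = generate_experimental_dataset(ExperimentGenConfig(seed=SEED))
    trials = gen.trials[~gen.trials["excluded"]]

    classifier = fit_gait_classifier(trials, seed=SEED)
    walk = fit_velocity_model(trials, "walk")
    run = fit_velocity_model(trials, "run")
    print(
        f"gait classifier: AUC {classifier.auc:.3f}, RSL threshold "
        f"{classifier.rsl_threshold:.2f}"
    )
    print(f"walk model: v = {walk.intercept:.3f} + {walk.slope:.3f} RSL "
          f"(RMSE {walk.rmse_mps:.3f} m/s)")
    print(f"run model:  v = {run.intercept:.3f} + {run.slope:.3f} RSL "
          f"(RMSE {run.rmse_mps:.3f} m/s)")

    _, summaries, _ = engare_sero_fixture()
    table = predict_assemblage(summaries, classifier, walk, run)
    table.to_csv(OUT / "speed_table.csv", index=False, float_format="%.10g")

    n_run = (table["gait"] == "run").sum()
    slow = ((table["gait"] == "walk") & (table["velocity_mps"] < 1.9)).sum()
    print(f"\n{len(table)} trackways: {n_run} running, {slow} walking below 1.9 m/s")
    print(table[["trackway_id", "rsl", "gait", "velocity_mps"]]
          .round(2).to_string(index=False))


if __name__ == "__main__":
    main()
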