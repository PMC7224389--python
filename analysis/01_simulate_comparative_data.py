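"""Generate the synthetic comparative datasets the downstream analyses fit.

The original experimental footprint trials (41 barefoot subjects, four
self-selected speeds) and the 3233-person anthropometric survey were
never publicly archived, so the pipeline is trained on synthetic
counterparts that match their published structure.  This script writes
both, plus a synthetic fossil assemblage with known ground truth, under
results/data/.
"""

from pathlib import Path

from trackways.data import write_trackway_table
from trackways.synthetic import (
    AssemblageGenConfig,
    ExperimentGenConfig,
    PopulationGenConfig,
    generate_anthropometric_population,
    generate_experimental_dataset,
    generate_fossil_assemblage,
)

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    exp = generate_experimental_dataset(ExperimentGenConfig(seed=SEED))
    kept = exp.trials[~exp.trials["excluded"]]
    exp.trials.to_csv(OUT / "experimental_trials.csv", index=False)
    exp.subjects.to_csv(OUT / "experimental_subjects.csv", index=False)
    print(
        f"experimental trials: {len(exp.trials)} generated, {len(kept)} kept "
        f"({exp.trials['excluded'].sum()} flagged excluded)"
    )

    pop, truth = generate_anthropometric_population(PopulationGenConfig(seed=SEED))
    pop.to_csv(OUT / "anthropometric_population.csv", index=False)
    n_m = (pop["sex"] == "male").sum()
    print(
        f"comparative population: {len(pop)} records ({n_m} male, {len(pop) - n_m} "
        f"female), growth plateaus at {truth['plateau_age_yr']}"
    )

    asm = generate_fossil_assemblage(AssemblageGenConfig(seed=SEED))
    write_trackway_table(asm.trackways, OUT / "synthetic_assemblage.csv")
    asm.truth.to_csv(OUT / "synthetic_assemblage_truth.csv", index=False)
    comp = asm.truth["category"].value_counts().to_dict()
    print(f"synthetic assemblage: {len(asm.trackways)} trackways, composition {comp}")


if __name__ == "__main__":
    main()
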