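"""Build the 26-feature gene matrix from somatic mutation and copy-number data.

Generates a small synthetic cohort (annotated variants, copy-number
segments, gene model, minimal common regions, prior gene scores, 21
pathway sets), builds the per-gene feature matrix, and contrasts an
average driver row with an average passenger row.
"""

import numpy as np

from driverank import SimulationConfig, simulate_genomics_cohort
from driverank.feature_builder import build_feature_matrix
from driverank.metapredictor import CVConfig, prepare_training_set, train_metapredictor
from driverank.io_formats import PREDICTOR_NAMES
from driverank.synthetic_fixtures import simulate_metapredictor_data
from driverank.metapredictor import stratified_split

# a quick metapredictor (the first feature depends on it)
table = simulate_metapredictor_data(SimulationConfig(seed=7))
rows = [
    (
        tuple(None if np.isnan(v) else float(v) for v in r[list(PREDICTOR_NAMES)]),
        r["label"],
    )
    for _, r in table.iterrows()
]
train, _ = stratified_split(prepare_training_set(rows), 0.75, seed=7)
meta = train_metapredictor(train, "random_forest", CVConfig(folds=3, repeats=1), seed=7)

fixture = simulate_genomics_cohort(SimulationConfig(seed=7, n_genes=120))
task = fixture.task_names[0]
features = build_feature_matrix(
    fixture.variants,
    fixture.segments,
    fixture.genes,
    fixture.mcr_regions,
    fixture.prior_scores[task],
    fixture.pathways,
    meta,
)
print(f"feature matrix: {features.shape[0]} genes x {features.shape[1]} features")

is_driver = features.index.isin(fixture.truth_genes)
summary = features.groupby(is_driver).mean().T.rename(
    columns={False: "passenger_mean", True: "driver_mean"}
)
print(summary.head(5).round(3))
print(
    "Driver genes show higher coding-impact maxima, more hotspot/double-hit "
    "flags and larger prior scores; the 21 pathway-membership columns "
    "(not shown) are similarly enriched."
)
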