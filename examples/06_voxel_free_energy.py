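"""From orientation samples to a solvation free-energy contribution.

Builds a synthetic table of position-tagged water orientations (uniform,
i.e. bulk-like: the true contribution is zero), voxelizes it on the
standard 10x10x10 grid of 0.5 A cells, estimates the relative orientational
entropy per voxel and converts it to -T dS_orient in kcal/mol.
"""

import numpy as np
import pandas as pd

from rotent import (
    Metric,
    MetricSpec,
    SymmetryMode,
    VoxelGrid,
    grid_entropy_report,
    sample_uniform,
    voxelize,
)
from rotent.solvation import QUAT_COLS

rng = np.random.default_rng(7)
n_frames, per_frame = 400, 120
n = n_frames * per_frame
df = pd.DataFrame({"frame": np.repeat(np.arange(n_frames), per_frame)})
df[["x", "y", "z"]] = rng.uniform(-2.5, 2.5, size=(n, 3))
df[QUAT_COLS] = sample_uniform(n, rng)

vox = voxelize(df, VoxelGrid())
report = grid_entropy_report(vox, "knn", 1, MetricSpec(Metric.D3, SymmetryMode.C2V))
occupied = report[np.isfinite(report["h_rel"])]

print(f"{n} samples over {n_frames} frames; {len(occupied)} of 1000 voxels estimable")
print(f"mean voxel occupancy n_bar = {occupied['n_bar'].mean():.3f} molecules/frame")
print(f"mean voxel H_rel = {occupied['h_rel'].mean():+.3f} nats")
print(f"total -T dS_orient = {report['minus_T_dS'].sum():+.4f} kcal/mol (bulk truth: 0)")
print("\nat ~50 samples per voxel the KNN estimate carries a small positive bias,")
print("which the conversion turns into a small spurious negative total; longer")
print("sampling per voxel shrinks both (see the sample-size sweep benchmark)")
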