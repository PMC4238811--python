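"""Entropy of uniformly random orientations — the null experiment.

Uniform (Haar) rotations have relative entropy zero. The k=1 KNN estimate
under the geodesic metric lands within a few hundredths of zero at modest
sample sizes, while the histogram carries a small negative occupancy bias
of about -(N_bins - 1)/(2n).
"""

import numpy as np

from rotent import (
    Metric,
    MetricSpec,
    SymmetryMode,
    histogram_entropy,
    knn_entropy_relative,
    sample_uniform,
)

rng = np.random.default_rng(7)
q, euler = sample_uniform(12_800, rng, SymmetryMode.C1, return_euler=True)

knn = knn_entropy_relative(q, k=1, spec=MetricSpec(Metric.D3, SymmetryMode.C1))
hist = histogram_entropy(euler, SymmetryMode.C1)

print(f"n = {knn.n} uniform rotations (true H_rel = 0)")
print(f"KNN (k=1, geodesic):  {knn.h_rel:+.4f} nats")
print(f"histogram (256 bins): {hist.h_rel:+.4f} nats "
      f"(expected bias ~ {-(256 - 1) / (2 * 12800):+.4f})")
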