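"""Why KNN entropy estimation needs independent samples.

A rotational random walk emulates molecular-dynamics snapshots: every
marginal is exactly uniform (true H_rel = 0), but consecutive orientations
are highly correlated, so each point's nearest neighbor is its temporal
neighbor and the KNN estimate collapses far below zero. Subsampling the
same fixed-length series trades samples for independence and restores the
estimate; the histogram instead degrades as the sample count shrinks.
"""

import numpy as np

from rotent import (
    CorrelationSpec,
    Metric,
    MetricSpec,
    SymmetryMode,
    histogram_entropy,
    knn_entropy_relative,
    quaternion_to_euler,
    sample_correlated_series,
    subsample,
)

rng = np.random.default_rng(7)
series = sample_correlated_series(CorrelationSpec(step_sigma=0.05, n_steps=25_600), rng)

print(f"{'interval':>8} {'n':>6} {'knn_d3':>8} {'histogram':>10}")
for interval in (1, 4, 16, 64, 256):
    sub = subsample(series, interval)
    knn = knn_entropy_relative(sub, 1, MetricSpec(Metric.D3))
    hist = histogram_entropy(quaternion_to_euler(sub), SymmetryMode.C1)
    print(f"{interval:>8} {len(sub):>6} {knn.h_rel:8.3f} {hist.h_rel:10.3f}")
print("\ntrue H_rel = 0: the KNN bias shrinks with subsampling (independence),")
print("the histogram bias grows (fewer samples) — an optimum lies in between.")
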