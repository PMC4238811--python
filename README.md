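# rotent

Orientational entropy estimation for distributions of 3D rotations.

`rotent` is for molecular modellers and structural bioinformaticians who
need the *relative orientational entropy* of a set of orientations — most
prominently the solute–water orientational term of inhomogeneous fluid
solvation theory (IFST), where the ordering of water molecules around a
solute is converted into a solvation free-energy cost. It provides:

* a **k-nearest-neighbor (KNN) entropy estimator** on the rotation group
  under four distance metrics — Euler-chart Euclidean (Δ1), quaternion
  difference (Δ2), geodesic / relative rotation angle (Δ3), and deviation
  from the identity matrix (Δ4) — with the C2v water symmetry handled
  throughout;
* a reference **Euler-angle histogram estimator** (45° equal-volume bins);
* **bias-controlled rotation samplers** whose true entropies are known in
  closed form (uniform Haar rotations; a divisor bias with `H = −ln A`; a
  geodesic-cap restriction with `H` from the S³ cap-area formula; and an
  autocorrelated rotation time series standing in for MD snapshots);
* a **benchmark harness** that replicates the published validation tables
  for these estimators, and
* a **solvation layer** (orientation-table I/O, voxelization, and the
  conversion `−T ΔS_orient = −T k N_A n̄ H_rel` in kcal/mol), plus a thin
  CLI (`rotent simulate|estimate|benchmark|voxelize`).

## The estimator

For `n` sampled orientations with distance `R_{i,k}` from sample `i` to its
k-th nearest neighbor (`p = 3` rotational degrees of freedom):

    H_abs = (p/n) Σ_i ln R_{i,k} + ln(π^{p/2}/Γ(p/2+1)) + ln n + γ − L_{k−1}
    H_rel = H_abs − ln Ω,     Ω = 8π² (C1)  or  4π² (C2v)

`H_rel ≤ 0` measures ordering relative to the uniform (Haar) distribution;
it is asymptotically unbiased for k = 1 and the geodesic metric, because
small geodesic balls on the rotation group have exactly Euclidean volume
`(4π/3) r³`. The quaternion metrics Δ2/Δ3/Δ4 are monotone functions of the
same inner product |⟨q₁,q₂⟩| and share nearest-neighbor graphs; nearest
neighbors are found by an exhaustive chunked scan that applies the
transcendental function only to the selected neighbor. See
`docs/methods.md` for the full account.

## Worked example

Recovering a known entropy from biased rotations (`examples/03_biased_truth_recovery.py`):

```
$ python examples/03_biased_truth_recovery.py
     A     true   knn_d3  histogram
     2    -0.69    -0.68      -0.69
    16    -2.77    -2.74      -1.39
   256    -5.55    -5.52      -1.39
  4096    -8.32    -8.25      -1.39

knn_d3 follows -ln A; the histogram cannot resolve past one bin (-1.39).
```

Each row draws 25,600 rotations whose density is compressed into a fraction
1/A of orientation space, so the true relative entropy is −ln A nats. The
k = 1 geodesic KNN estimate tracks the truth to a few hundredths of a nat
even for sharply peaked distributions, while the 128-bin histogram
saturates at −ln 4 = −1.39 as soon as the feature is finer than one bin —
the resolution failure that motivates the KNN approach. The other examples
cover the metrics themselves, the uniform null case, the cap restriction,
the correlated-series failure mode of KNN estimation, and the per-voxel
free-energy report.

The same experiments from the shell:

```sh
rotent benchmark table1 --repeats 50 --seed 1 -o table1.tsv
rotent simulate --sampler uniform -n 12800 --seed 3 -o bulk.tsv
rotent estimate bulk.tsv --estimator knn --metric d3 -k 1
```

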