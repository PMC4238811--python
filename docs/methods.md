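# Methods

## Problem

`rotent` estimates the *relative orientational entropy* of a set of 3D
orientations: the Shannon entropy relative to the uniform (Haar)
distribution over the rotation group, in nats,

    H_rel = - ∫ g(ω) ln g(ω) dω / Ω  ≤ 0,

where `g` is the orientational correlation function (density relative to
uniform) and `Ω` the total angular volume. `H_rel = 0` for an isotropic
distribution and becomes more negative the more the orientations are
ordered. In inhomogeneous fluid solvation theory (IFST) this quantity,
evaluated for water molecules in small voxels around a solute, gives the
solute–water orientational contribution to the solvation free energy; only
this term is treated here (translational and water–water terms are not).

## Rotation representations

Orientations are unit quaternions `(w, x, y, z)` with the double cover
`q ~ -q` respected by every consumer. The Euler chart is intrinsic
z–y′–z″ `(α, β, γ)` with ranges `[0, 2π) × [0, π] × [0, 2π)`; in this chart
the Haar measure is `dα d(cos β) dγ`, which makes uniform sampling and
equal-volume histogramming elementary. The reference orientation for a
water-like molecule puts the C2 (bisector) axis along +z and the in-plane
H→H axis along +y; `water_body_frame` returns the rotation carrying the
reference frame onto a molecule given O/H/H coordinates.

At gimbal lock (`|cos β| = 1`) the chart is degenerate; the convention is
`γ = 0` with the surviving spin folded into `α`. Chart-independent code
paths (all quaternion metrics) are unaffected.

### C2v symmetry

A water molecule is physically unchanged by a π spin about its C2 axis, so
orientation space halves: `γ` is defined modulo π, the angular volume drops
from `Ω = 8π²` to `4π²`, and every distance is minimized over the image pair
`{q, q⊗s}` with `s` the π body-z spin. The C2 action is free, so the
quotient is locally isometric to the full rotation group and the KNN
calibration below is unchanged. Note the quotient's *diameter* is still π
(a π flip about an in-plane laboratory axis is equidistant from both images
of the identity); symmetrization shrinks small distances' multiplicity, not
the global range.

## Distance metrics

Four metrics on rotations, all invariant to `q → -q`:

| metric | definition | range |
|---|---|---|
| Δ1 | Euclidean in the Euler chart: wrapped dα, d(cos β), wrapped dγ | [0, √(4+2π²)] |
| Δ2 | `2·min(‖q1−q2‖, ‖q1+q2‖) = 2√(2−2\|⟨q1,q2⟩\|)` | [0, 2√2] |
| Δ3 | geodesic: relative rotation angle `θ = 2 arccos\|⟨q1,q2⟩\|` | [0, π] |
| Δ4 | `‖I − R1R2ᵀ‖_F / √2 = 2 sin(θ/2)` | [0, 2] |

Δ2 and Δ4 agree with the natural metric Δ3 to first order in θ, so the
three share nearest-neighbor graphs exactly (they are monotone decreasing
functions of the same inner product). Δ1 is *not* equivalent to the
geodesic metric: two nearly identical rotations can sit far apart in the
Euler chart, which is the failure mode the benchmarks quantify.

Two normalization choices deserve note. In Δ1 the second coordinate is the
difference of `cos β` (not `β`): this is the combination under which the
chart carries the uniform measure and the only one whose maximum is
√(2² + π² + π²), the documented range. Δ4 is the Frobenius deviation from
the identity divided by √2; the raw deviation has range [0, 2√2] and the
scaling is the unique constant giving range [0, 2] while preserving
small-angle agreement with Δ3.

## Nearest-neighbor search

Distances `R_{i,k}` to the k-th nearest other sample point are found by an
exhaustive O(n²) scan, chunked to bound working memory. Neighbors are
ranked by a *monotone surrogate* — the absolute quaternion inner product
for Δ2/Δ3/Δ4 (one pass serves all three), the squared wrapped chart
distance for Δ1 — and the sqrt/arccos is applied only to the selected
neighbor. Optional numba kernels accelerate the common k = 1 case; the
chunked numpy path is the reference and the general-k path, and the two are
tested for equivalence against a naive full-sort search. Ties rank by
lowest sample index. Inner products are clamped to [0, 1], and values
within 5e-15 of 1 are snapped to 1 so that bitwise-duplicate orientations
sit at distance exactly zero (and are then rejected, see below).

At the benchmark size n = 25,600 one scan costs a few seconds on one core;
no spatial data structure is used.

## KNN entropy estimator

With `p = 3` rotational degrees of freedom,

    H_abs = (p/n) Σ_i ln R_{i,k} + ln V_p + ln n + γ − L_{k−1},
    V_p = π^{p/2} / Γ(p/2+1) = 4π/3,   L_m = Σ_{j≤m} 1/j,  γ = 0.5772…

and `H_rel = H_abs − ln Ω` with `Ω = 8π²` (C1) or `4π²` (C2v). The
calibration rests on the geodesic ball volume: on the rotation group a ball
of radius r (in Δ3) has Haar volume `V₃ r³ (1 − r²/20 + …)`, so the
Euclidean-ball constant is exact as r → 0 and the estimator is
asymptotically unbiased. The curvature correction also explains the
observed finite-k structure on uniform data: ball volumes grow slower than
`r³` for Δ3 (positive bias growing with k), slightly slower for Δ2, and
faster for Δ4 (negative bias), which is exactly the sign pattern the k
sweep reproduces.

The `ln n` term uses n rather than n−1; at the benchmark sizes the
difference (< 1.3e-5 nats) is orders of magnitude below the repeat SD, and
the replication results are insensitive to the choice.

Zero NN distances (duplicate orientations) raise `DuplicateSampleError`
rather than being floored: duplicates signal perfectly correlated input,
for which the density estimate diverges; callers with time-series data
should subsample instead.

## Histogram estimator

Equal-volume bins in `(α, cos β, γ)`, 45° per angular bin: 8×4×8 = 256 bins
(C1) or 8×4×4 = 128 bins (C2v, γ modulo π). With occupancy fractions `f_b`,

    H_rel = − Σ_b f_b ln(f_b · N_bins),   0 ln 0 := 0,

which is ≤ 0 with equality iff all bins are equally occupied. Bins are
half-open `[low, high)` with the top bin closed, so boundary samples bin
deterministically. The estimator has a resolution floor — any density
feature sharper than one bin reads as one bin — and a small-sample bias of
roughly `−(N_bins − 1)/(2n)` on uniform data.

## Synthetic generators and their analytic truths

All benchmark inputs are generated internally; every generator takes a seed
and identical seeds reproduce identical samples.

**Uniform.** `α = 2π r₁`, `cos β = 2r₂ − 1`, `γ = 2π r₃` (`π r₃` in C2v)
from i.i.d. uniform `r_i`; the pushforward is Haar. Verified against the
closed-form geodesic distance density `(1 − cos θ)/π` and cap fractions.

**Divisor-A bias.** `r₂ → r₂/A` compresses `cos β` into `[−1, −1+2/A]`,
giving an A-fold density on 1/A of the space and zero elsewhere:
`H_rel = −ln A` exactly, in either symmetry mode. This choice of biased
coordinate makes three documented numbers emerge at once: the exact truth
−ln A; the histogram saturation at −ln 4 = −1.39 for A ≥ 4 (the slab fits
inside one of the four cos β bins); and the Δ1 plateau (below).

**Geodesic-cap bias.** Uniform proposals farther than `Δmax = π/B` (plain
Δ3) from a reference are rejected. The retained probability fraction
follows from the S³ cap area: with `φ = π/(2B)`,
`fraction = (2/π)(φ − sin φ cos φ) = I(sin²φ; 3/2, 1/2)`, and
`H_rel = ln fraction`. The trigonometric form is the implementation; the
regularized-incomplete-beta form is the cross-check in the tests. The cap
study runs in C1 mode (full rotation space, Ω = 8π²): the analytic truth is
the symmetry-free cap fraction, and for B ≥ 2 the C2v image of any in-cap
rotation lies outside the cap, so symmetrization would not change the
distances anyway.

**Correlated series.** A rotational random walk emulating MD snapshots:
uniform initial orientation (so every marginal is exactly Haar), each step
a rotation about a fresh uniform axis by a half-normal angle of scale
`step_sigma` (default 0.05 rad, chosen so that at the default length 25,600
the one-step neighbor distance ≈ 0.04 sits well below the independent-
sample NN spacing ≈ 0.11, reproducing the correlation failure of the KNN
estimator). This generator reproduces qualitative phenomena only — real
water dynamics has librational structure, anisotropic rotational diffusion
and hydrogen-bond exchange kinetics that a geodesic random walk does not
emulate — so tests assert directions and orderings, never numbers, against
it. One consequence: "the histogram is insensitive to temporal correlation"
holds only relatively (correlation inflates bin-count variance, hence some
histogram bias); the tests therefore assert that the histogram shift is
small compared with the KNN shift at equal n.

### The Δ1 plateau

For large A the biased samples form a slab thinner than the neighbor
spacing: the data are effectively 2-D (uniform on the `(α, γ)` torus) while
the estimator assumes 3-D scaling. A Poisson argument for the NN distance
on a torus of area `S` gives a plateau of

    H_rel = −(1/2) ln n + (3/2) ln(S/π) − γ/2 + ln(4π/3) − ln Ω,

which at n = 25,600 in C2v mode (`S = 2π²`, `Ω = 4π²`) evaluates to −4.85 —
the replicated plateau value. The plateau depends on which coordinate the
bias compresses and on the symmetry mode (C1 would give −4.50), so it is
asserted only under this package's documented generator.

## Benchmarks

`run_repeats` regenerates the sample independently per repeat from spawned
child streams (results are independent of which estimators are attached)
and reports mean and sample SD. Defaults: 50 repeats (the SD of a
50-repeat mean at n = 25,600 is ≈ 0.0015 nats, far below the 0.02-nat
comparison band; raising `n_repeats` to 1000 is supported but changes
nothing at the reported precision). The divisor-A table runs in C2v water
mode, the cap-B table in C1, the k and n sweeps in C2v, and the interval
sweep holds the series length fixed so larger subsampling intervals leave
fewer samples — the trade-off that produces an optimal sampling frequency
for correlated data.

## Free-energy conversion

For a voxel with mean per-frame occupancy `n̄`,

    −T ΔS_orient = −T (k N_A) n̄ H_rel   [kcal/mol],

with T = 298 K and `k N_A` = 1.9872e-3 kcal/(mol K) by default. `H_rel ≤ 0`
makes the contribution non-negative: orientational ordering always costs
free energy. The grid total is the sum over voxels. Voxels with fewer than
k+1 samples are reported as NaN entropy and excluded from the total; `n̄`
is computed from the file's frame column as (voxel count)/(number of
distinct frames).

## Numerical choices and limitations

* Quaternion sign: canonicalized to `w ≥ 0` (first non-zero component
  positive on ties) for serialization only; all computations are
  sign-invariant.
* Collinearity in `water_body_frame` is rejected when the cross product of
  the bond directions has norm below 1e-8.
* Parsed quaternions must be unit to 1e-6; they are renormalized after the
  check.
* The exhaustive NN search is O(n²); beyond ~10⁵ samples a spatial index
  would be preferable but is outside scope.
* Passing the synthetic benchmarks demonstrates estimator correctness on
  independent, exactly-Haar-or-analytically-biased data. It does not
  demonstrate accuracy on real MD data, where temporal correlation (shown
  here to bias the KNN estimate downward until subsampled) and finite
  trajectory length dominate the error budget.
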