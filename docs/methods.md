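# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `mapalign`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Diffusion maps

Each frame and metric yields an `n × n` distance matrix `D`. The affinity
is the self-tuning Gaussian k-nearest-neighbor kernel
`K(x,y) = exp(−d(x,y)²/(d(x,k(x)) d(y,k(y))))` with the bandwidth at each
point its distance to its `k_nn`-th nearest neighbor, **excluding the
point itself** (self-inclusion would make `k_nn = 1` degenerate). The
kernel is exactly invariant to a global rescaling of `D` (verified to
1e−12 in tests). `k_nn` defaults to 7 — small enough to stay local at the
group sizes studied (n ≈ 70–500), large enough that the bandwidth is not
dominated by a single neighbor; results are insensitive to moderate
changes.

Duplicate agents make a bandwidth zero; this raises by default, naming the
offending pair. Pipelines run with a tolerant mode that floors bandwidths
at `1e−12 × median(D)`, since tracked data occasionally contains
coincident detections.

Normalization follows the α = 1 (density-invariant) convention: divide by
the row-sum vector on both sides, then set row sums to one, giving the
Markov operator `Â`. The eigensolve is performed on the symmetric
conjugate `S = D^{1/2} Â D^{−1/2}` (`D` = diagonal of the intermediate row
sums): this guarantees a real spectrum, and — crucially — a Euclidean
**orthonormal** eigenbasis, which is what the analytic beta null of the
alignment statistic assumes. (The right eigenvectors of the nonsymmetric
`Â` itself are unit-normalized but not orthogonal; they are available via
an option for comparison experiments.) Eigenpairs are sorted by descending
eigenvalue with stable tie order; each eigenvector's sign is fixed by
making its largest-magnitude entry positive.

The trivial eigenpair (λ ≈ 1, the geometry-free stationary mode) is
removed by default, so "mode 1" always means the first informative
coordinate. Retaining it would mechanically inflate the alignment between
any two metrics, since every heat operator shares it. More than one
eigenvalue within 1e−10 of 1 indicates a disconnected affinity graph; the
basis is flagged and a structured warning emitted rather than failing.

Diffusion time is fixed at `t = 1` throughout (configurable). Spectral
reconstruction of `Â^t` from the full decomposition matches direct matrix
powers to better than 1e−8 on random point clouds up to n = 50 (the
acceptance script reports ~1e−15).

## Metrics

* **Spatial proximity** `d⁽¹⁾`: Euclidean distance at the frame, planar or
  toroidal (per-axis minimum of `|Δ|` and `L−|Δ|`).
* **Velocity-profile distance** `d⁽²⁾`: kernel-smoothed L2 distance of the
  two agents' recent velocity series,
  `d² = Σ_{s<w} κ_s ‖v_i(t−s) − v_j(t−s)‖²`, with exponential-decay
  weights `κ_s ∝ exp(−s/τ)` normalized to sum to one. Defaults `w = 10`
  frames, `τ = 5` frames: the profile covers the "recent period" of
  motion, with newer frames weighted more. The normalization makes a
  constant velocity offset `u` yield distance `‖u‖` exactly.
* **Lagged variant**: for following/leading interactions, the profile
  distance is minimized over a relative shift `ℓ ∈ {0..ℓ_max}` applied to
  *either* agent's profile (the minimum over both assignments makes the
  matrix symmetric by construction, which the kernel requires). Enlarging
  `ℓ_max` can only decrease entries (tested). Default `ℓ_max = 60` frames
  = 2 s at the 30 fps assumed for fish-like data; 0 for simulation data.
  Lag search costs one `n × n` distance evaluation per lag, implemented as
  a single `cdist` on stacked √κ-weighted profile vectors per lag.

Agents missing any frame of the required `w + ℓ_max` history are dropped
from that frame's analysis and logged; the trajectory reader indexes
per-agent presence runs to make this cheap.

## Alignment statistic and its null

Squared projections of the first-basis modes onto the leading-`k` span of
the second basis are standardized by the null moments `k/n` and
`2(n−k)k/(n³+2n²)`; the corresponding Beta shape pair is
`(k/2, (n−k)/2)` — the unique pair reproducing those moments (the reversed
order occasionally quoted for this law would give mean `(n−k)/n` and is
inconsistent; `NullModel.note` records this). Monte-Carlo calibration at
`n = 200, k = 15` over 5000 draws: empirical mean and variance of the
squared projection within 3 standard errors / 10% of the analytic values,
Kolmogorov–Smirnov p ≫ 0.01, and the standardized summands have mean
within ±0.05 and variance within 10% of 1.

`Z_k` weights the `k` standardized projections by the first basis's
normalized eigenvalue vector `û` (taken from the retained,
post-trivial-removal spectrum at `t = 1`). The same `k` is used for the
projection rank, the weight length and the summation range. If all `k`
leading eigenvalues are ≈ 0 (e.g. a uniform operator), `û` is undefined;
the statistic returns 0 with an `unweightable` flag instead of dividing by
~0. The statistic is asymmetric; the pipeline computes both directions and
gates on the forward direction `Z(position, velocity)`, matching the
convention used for the gate threshold.

**Known bias.** Both diffusion bases are orthogonal to their (removed)
trivial modes, which are nearly the same vector; the effective ambient
dimension is therefore `n − 1` rather than the `n` the null assumes. On
independent random geometries this produces a small positive offset of
`Z_10` (≈ +0.1 at n = 100–200, shrinking with the per-summand bias
`≈ k/(n(n−1)) × scale`), far below the coherence gate of 3 and within the
Monte-Carlo 3-SE band at 200 repetitions. It is left uncorrected to keep
the standardization exactly as defined.

**Choosing k.** The tail of a diffusion spectrum typically decays like
`C j^(−β)`; `suggest_k` least-squares-fits the tail on log–log axes over
candidate cut points and returns the smallest cut whose tail deviates from
its fit by < 20% relative error everywhere, plus (given several frames) a
cross-frame stability diagnostic of the variance-explained fractions
`λ_j/Σλ`. These are rough guidelines; overestimating `k` is benign because
additional summands are near-independent of the leading modes, so `Z_k`
stabilizes (tested on constructed examples). The presets use `k = 10` for
flocking runs and `k = 15` for fish-like data, robust over roughly 10–25.

## Macrostate classification

Frame fingerprints are the `k²` inner products
`ξ_{ij} = λ_i⁽¹⁾λ_j⁽²⁾⟨φ_i⁽¹⁾, φ_j⁽²⁾⟩` of the truncated diffusion
coordinates, taken in absolute value and sorted in decreasing order
(ties broken by row-major original index). Sorting removes the sign and
index instability of eigenvectors under small operator perturbations; the
result is invariant to any sign flip and bounded entrywise by
`λ_i⁽¹⁾λ_j⁽²⁾` (Cauchy–Schwarz).

Frames with `Z_k < 3` (three null standard deviations — an ad hoc but
natural threshold, configurable) are labeled incoherent (`N`). Remaining
fingerprints are clustered by k-means with `n_clusters = 3`, 10 seeded
restarts, best inertia kept. Cluster *names* G1, G2, … are assigned by
descending mean `Z` within cluster, so the naming reflects relative
organization rather than arbitrary k-means label order. Frames with fewer
than `min_n = 30` agents are excluded before analysis: the kernel and the
null both assume moderate `n`.

The reference classification uses the polarization
`O_p = |Σ v̂_i|/N` and rotation `O_r = |Σ (q̂_i × v̂_i)|/N` (scalar
z-component of the 2-D cross product; `q̂_i` = unit vector from the
centroid): milling if `O_p ≤ 0.35 ∧ O_r ≥ 0.65`, swarming if both ≤ 0.35,
polarized if `O_p ≥ 0.65 ∧ O_r ≤ 0.35`, else transitional. Zero-speed
agents contribute zero unit vectors (counted); agents at the centroid
contribute zero to `O_r`.

## Flocking simulator

Vicsek-type model on the unit torus: `N` agents at fixed speed `v`; each
step every agent adopts the circular mean heading (angle of the summed
unit vectors — arithmetic averaging of angles is wrong across the 2π wrap
and is not offered) of all agents within toroidal distance `r`, itself
included so the neighbor set is never empty, plus an independent
`N(0, ε²)` draw added after averaging; updates are synchronous. Standard
parameters `ε = π/5`, `v = 1/320`. Neighbor search is the naive O(N²)
pairwise computation, adequate for N ≤ ~1000.

The coupling schedule `r(t)` can be constant, a linear ramp (low plateau →
ramp → high plateau), or a sinusoidal chirp between `r0 = 0.0065` (far
below the ordering transition) and `r1 = 0.06` (well above it). The
experiment runner evaluates `Z_10(p, v)` along the run — position metric
toroidal, velocity-profile metric with `w = 10`, no lag — and a
multi-trial runner aggregates the mean and the empirical 5th–95th
percentile band across seeds.

Problem sizes for the standard transition experiment were chosen to keep
a full re-run cheap: 200 agents, 600 steps with the ramp over steps
240–360 (the same 2:1:2 low/ramp/high proportions as the full-scale
protocol), 10 trials. Measured on the first and last 100 steps, the ramp
raises mean `Z_10` by ≈ 25–30 null standard deviations while the
polarization rises in every trial; the acceptance script recomputes both.

## Synthetic school sessions

No public fish-school trajectory dataset matches the statistical structure
the method targets, so the `fixtures` module generates kinematic
stand-ins with unambiguous ground truth. The generators are deliberately
*not* the Vicsek simulator — regime labels must not depend on the dynamics
the method is later asked to detect.

* **milling** — noisy circular orbits (random radii 0.3–0.6, common
  angular speed 0.04 rad/frame) about a common center; tangential motion
  makes velocity direction a smooth function of angular position, so the
  two geometries are strongly codetermined.
* **swarm** — independent jittered random walks (fresh uniform heading
  each frame) with near-zero net motion; the two geometries are unrelated.
* **polarized-single** — one group with a slowly drifting common heading.
  Agent-level structure comes from two smooth spatial fields tied to the
  motion frame: headings vary front-to-back along the travel direction
  (leader/follower structure) and speeds vary laterally (flank bands),
  both sinusoidal with wavelength 2.4 (monotone-ish across the ~0.8-unit
  group) plus small iid noise. This gives the velocity geometry a genuine,
  stable positional organization, as in a real traveling school.
* **polarized-split** — two subgroups whose mean headings oscillate in
  antiphase around the common heading (±30° × sin(2πt/100)), so they
  follow distinct weaving paths while staying spatially intermingled, and
  whose internal fields have independent phases across subgroups. The
  regime is *defined* as less internally organized — field amplitudes at
  1/3 of the single-group values and heading noise 0.12 rad — matching the
  defining signature of multi-subgroup ("β"-style) polarized motion: a
  macro-scale division in the velocity network without a matching division
  in the position network, hence systematically lower alignment than
  unified ("α"-style) travel.

Arena units are roughly meters at 30 fps; speeds (0.02 units/frame ≈
0.6 m/s) and group sizes (70–280) match the scale of tracked shiner
schools. Each generated segment self-checks that ≥ 90% of its frames land
in its regime's `O_p/O_r` box and regenerates from a fresh substream
otherwise (≤ 5 retries, then an error reporting the achieved fractions).
Velocities are stored as central finite differences of positions
(`numpy.gradient` convention), so re-deriving them from positions is
exact; on a zero-noise, equally spaced mill the interior-frame velocities
are exactly tangential and `O_r = 1` to rounding.

`standard_session` concatenates one segment per regime with fresh agent
identities per segment — modeling fish entering/leaving the tracked field
of view — and draws segment sizes as a session-level base count with ±25%
per-segment fluctuation. (A single school's visible count fluctuates
around its actual size; independent uniform draws over the full 70–280
range would instead model four unrelated schools, and would confound
cross-segment comparisons of `Z`, whose scale grows with `n`.)

**What the fixtures do and do not show.** Passing the end-to-end tests
(all swarm frames gated; milling vs. single-group polarized separated with
full purity; split-group mean `Z` below single-group mean `Z` in every
session) shows the pipeline recovers macrostates whose defining structure
is present by construction. Real schooling data differs in ways the
fixtures do not model: gradual transitions between regimes (fixtures
switch discretely at segment boundaries), within-segment tracking gaps,
interaction-driven fluctuation correlations richer than two smooth fields,
and observation noise. The gap-handling path is tested separately with
masked frames.

## Numerical conventions and degenerate inputs

* Distance matrices are validated (symmetric to 1e−8, nonnegative, zero
  diagonal) then exactly symmetrized; affinities likewise, with unit
  diagonal. Kernel underflow to exact 0 for very distant pairs is
  tolerated.
* Eigenvalue ties: stable sort order of the symmetric solver after the
  descending sort; covariance-vector ties: row-major original index.
* All randomness flows through explicit `numpy.random.Generator` objects
  or integer seeds recorded in configs; identical inputs and seeds give
  bit-identical results (tested). Pipeline outputs embed a SHA-256 hash of
  the resolved configuration.
* Frames failing any precondition (too few agents, missing history,
  degenerate kernel) are logged and skipped, never fatal; a run with zero
  analyzable frames raises and names the limiting constraint.

## Limitations

* The statistic's scale grows roughly linearly with `n` at fixed geometric
  alignment, so `Z` values are comparable across frames of similar size
  but not across very different group sizes; the gate at 3 is a
  significance threshold, not an effect size.
* Dense eigensolves limit practical group sizes to a few thousand agents
  per frame.
* The scale-free kernel cannot distinguish an extremely organized state
  (velocity cloud collapsed to a point, structure = noise ratios) from an
  unorganized one by scale alone; tracking a raw scale statistic (e.g.
  mean inter-agent distance) alongside `Z` is advisable in applications.
* Only 2-D planar and toroidal geometries are implemented.
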