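# Methods

## Problem and model

`fedrff` simulates federated population density estimation. A server wants
the density surface of `N` users' locations `d_i ∈ ℝ²` (or ℝ¹) on a P×Q
grid over a rectangular area `A`, without collecting the locations. The
underlying estimator is kernel density estimation with the Gaussian kernel

    k_h(x, y) = exp(−‖x − y‖² / (2 h²)),

used **unnormalized** throughout the protocol: each exact per-user response
then peaks at 1 at the user's own location, and both evaluation metrics used
here (Spearman rank correlation and the localization-attack score) are
invariant to the constant `1/(2πh²)`. `gaussian_kernel(..., normalized=True)`
supplies the unit-integral form for direct comparison against true
densities.

In **exact mode** (federated KDE) user `i` returns `k_h(d_i, g)` at every
grid node `g` and the server averages responses — numerically identical to
pooled KDE, but each response is a bump centered at the user, so a malicious
server reads off `d_i` to grid precision. This is the zero-privacy baseline.

In **RFF mode** each user projects their location onto `B` random Fourier
features. By Bochner's theorem `k_h(x,y) = E_ω[cos(ωᵀ(x−y))]` for
`ω ~ N(0, h⁻²I)`, so the response `Σ_b cos(ω_bᵀ(g − d_i))` is an unbiased
Monte-Carlo estimate of `B·k_h(d_i, g)`; the server's pooled average
`(1/NB) Σ_{i,b} cos(ω_ibᵀ(g − d_i))` converges to the pooled KDE surface as
either `N` or `B` grows (users and features are nearly exchangeable at
fixed budget `N·B`). Privacy comes from each cosine feature being spatially
delocalized: a single projection value identifies only a family of parallel
bands spaced `2π/‖ω‖`, not a point.

## Frozen frequencies and bandwidth rescaling

Each user draws frequencies **once**, at a base bandwidth `h0`, and never
redraws them; `RFFBasis` stores them write-protected. A query at bandwidth
`h` is answered with the rescaled frequencies `(h0/h)·ω`, which are exactly
`N(0, h⁻²I)` distributed — so estimation quality is unaffected — while band
*directions* never change across queries. Consequently:

* repeated identical queries return bit-identical surfaces;
* a moving user's responses are rigid translates of one another (the server
  cannot anchor the pattern, so it learns neither position nor travel
  direction);
* multi-bandwidth queries are constrained by a user-side policy.

The RNG contract: one master seed; user `i`'s basis comes from
`SeedSequence(master, spawn_key=(i,))`, so any user's surface is
reproducible independently of iteration order, and the streaming
whole-population driver (`federated_rff_surface`) is bit-identical to the
per-user `user_surface_rff` + `aggregate` path (tested).

## Bandwidth policy

`BandwidthPolicy(h0, gamma, j, l, B_max)` lets a user refuse improper
queries unilaterally; refusal depends only on public parameters, revealing
nothing about the location.

* **Maximum bandwidth.** For one 2D feature, `‖ω‖² ~ h⁻² χ²₂`, and at least
  `l‖ω‖/(2π)` bands cross the inscribed square of side `l` (the worst,
  axis-aligned orientation with a corner user). Requiring at least `j`
  bands with probability `1 − C(γ)` (`C` the χ² CDF with 2 df) gives
  `h_max = √γ · l / (2πj)`. The `√γ` placement is forced by dimensional
  analysis of the χ² threshold; `band_count_probability` is an independent
  Monte-Carlo check that the guarantee holds at `h = h_max` (it does, with
  slack, since generic orientations produce more bands than the worst
  case). `j ≥ 2` is enforced — with at least three bands present a corner
  user always shares a long central band.
* **Rescaling set.** Query bandwidths must be of the form `(4n+1)·h0`.
  Then every band of the rescaled response coincides with a base-bandwidth
  band (one in every `4n+1`), so intersecting responses across compliant
  bandwidths still leaves `⌊m/(4n+1)⌋` candidate bands. An off-policy
  ratio such as `2.5·h0` produces bands that fall *between* base bands;
  those shifted bands are eliminable by an attentive server, and an
  irrational ratio collapses the intersection to the user's own band (both
  behaviours are demonstrated in the adversary tests). `n = 0` (the base
  bandwidth itself) is accepted; membership uses relative tolerance 1e−9
  to absorb decimal round-trips through config files.

## The attack and the privacy score

The attacker model is maxima inference: the optimal location guess always
lies on a maximum of the response surface (the true location attains the
maximal feature value 1). `find_local_maxima` marks a cell a maximum iff
its value ≥ all existing neighbors (8-neighborhood in 2D; boundary cells
compare only the neighbors they have); adjacent qualifying cells are
necessarily equal-valued, and each such plateau is reduced to its
lowest-linear-index representative so the attack is deterministic.

`privacy_score_user` drops maxima weaker than `e_max/ε` (default ε = 1.1),
weights the survivors by their values, and reports

    Z_i = Σ_j e′_j · ‖g_j − d_i‖₂ ,   Σ_j e′_j = 1,

the attacker's expected localization error in map units. We implement the
weighted *average* (no extra `1/K_i` factor): that is the form with the
"expected error in units of distance" interpretation, and the one whose
exact-KDE value (≤ one grid spacing) and 0-feature value (mean distance to
all grid nodes) anchor the two ends of the privacy axis consistently. A
`double_normalize=True` option reproduces the literal double-normalized
variant. Degenerate all-nonpositive surfaces (possible since RFF responses
can be negative) fall back to the unweighted mean over all maxima and are
flagged. The filter threshold `e_max` is taken over all local maxima — the
global maximum cannot be filtered against itself. The system score `Z` is
the plain mean of the `Z_i`.

Stronger attackers (continuous optimization off-grid, Bayesian priors over
the area, road-network side information) are out of scope.

## GeoInd baseline

The planar Laplace mechanism with density `(ε²/2π)e^{−ε‖x−x0‖}` is sampled
via its exact polar decomposition: radius `~ Gamma(2, 1/ε)` (mean `2/ε`),
angle uniform — equivalent to, and simpler than, the Lambert-W inverse-CDF
construction. Each location is perturbed exactly once per experiment
(one-shot release, matching the RFF protocol's single frozen response), and
perturbed points are not clipped to the area: at small ε users can land
outside it, which is why GeoInd privacy scores can exceed the 0-feature
bound.

## Synthetic data

The generators define the study conditions: `grid9` (9 isotropic Gaussians
on `{−1,0,1}²`, Σ = diag(0.25, 0.25), equal weights — smooth/uniform),
`octagon8` (8 anisotropic rotated ellipses `R(πi/4)diag(1, 0.16²)R(πi/4)ᵀ`
at radius 3 — heterogeneous), and `tri1d` (N(−10,2²), N(0,2²), N(5,2²)
with weights 0.2/0.6/0.2). Default evaluation grids: `[−3,3]²` at 50×50,
`[−5,5]²` at 100×100, and `[−15,15]` at 1000 points respectively; sweep
defaults are `h = 0.55`, `N ∈ {1000, 5000, 10000, 20000}`,
`B ∈ {1,…,8, 50}`, GeoInd `ε ∈ {0.6, 0.7, 0.8, 1, 3, 5, 10}`.

What the synthetic populations do **not** emulate: street-network
clustering, heavy-tailed check-in frequencies, repeated visits by the same
user, and geographic (degree) coordinates. Passing tests therefore show
protocol correctness and the shape of the privacy–utility trade-off, not
calibrated performance on real mobility data.

## Bandwidth-selection heuristic

`select_bandwidth` subsamples 10% of the points without replacement and
returns the mean distance to the k-th nearest neighbor *within the
subsample* (self excluded; k = 200 is a good synthetic-scale default, 500
suits large real datasets). An exact O(n²) brute-force oracle over the same
subsample verifies the cKDTree implementation.

## Evaluation harness

Utility = Spearman rank correlation across grid nodes (average ranks for
ties; constant surfaces are rejected — notably the 0-feature response has
no rank ordering and records `utility = None`). The reference surface is
configurable: true mixture density (synthetic convention) or pooled
exact-KDE surface (real-data convention). `gain_per_cost` reports
`(utility(B) − utility(1)) / (Z(1) − Z(B))` for B > 1 — the cost is written
as `Z(1) − Z(B)` so that giving up privacy is a positive cost; a zero cost
yields an `inf`/`nan` flag rather than an error. Sweeps are deterministic
per (cell, seed) regardless of execution order; per-cell privacy can be
estimated on a user subsample (`privacy_subsample`) to bound attack cost in
large sweeps.

## Numerical choices and problem sizes

* Whole-population drivers stream in chunks (≤ 8192 feature rows × grid
  nodes) so memory stays modest at any N·B.
* Grids are endpoint-inclusive `linspace`; index `[p, q] ↔ (x_p, y_q)`,
  linear index `p·Q + q`, fixed so surfaces serialize unambiguously.
* The band-overlap demonstration (`bandwidth_overlap_period`)
  sizes its 1D window adaptively to the drawn wavelength (≈ 2.6 rescaled
  periods each side, 26 nodes per base period) so the overlap pattern is
  resolvable for any non-degenerate frequency; draws with `|ω| < 1e−3` are
  rejected as unresolvable on a finite window.
* Headline checks run at the study sizes (N up to 20000, B up to 50,
  10-seed medians); trend tests in the unit suite use moderate sizes
  (N ≈ 2000, 3–5 seeds, privacy subsampling) chosen so medians are stable
  across reruns.

## Known limitations

* Latitude/longitude are treated as planar coordinates (degrees); no
  geodesic distances, so privacy scores on geographic data are in degrees.
* The attacker is the grid-maxima attacker; no continuous refinement.
* Dimensions above 2 are not supported (the policy analysis is 2D).
* The in-process "federation" enforces information boundaries by module
  discipline (aggregation consumes only surfaces), not by cryptography;
  secure aggregation and DP composition are out of scope.
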