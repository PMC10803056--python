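# fedrff — federated density estimation by projection on random features

`fedrff` is a simulation toolkit for **privacy-preserving federated
population density estimation**. A server wants the kernel density surface
of `N` users' locations on a P×Q grid, but the users never upload their
coordinates. In plain federated KDE each user returns the kernel
evaluations `k_h(d_i, g_pq) = exp(−‖d_i − g_pq‖²/2h²)` — a surface that
peaks at the user's own location, so a malicious server can localize every
user to grid precision. In **federated RFF KDE** each user instead returns
projections onto `B` frozen random Fourier features,

    G′(d_i)[p,q] = Σ_b cos(ω_bᵀ(g_pq − d_i)),   ω_b ~ N(0, h⁻²I),

and the server's average `(1/NB) Σ_i G′(d_i)` is an unbiased estimate of
the pooled KDE surface (Bochner's theorem). Each cosine feature is
*spatially delocalized* — its level sets are parallel bands repeating
across the whole map — so a single user's response pins them down only to
an equivalence class of bands, while the population-level average still
recovers the density.

The package implements, end to end:

* the exact and random-feature protocols with frozen per-user frequency
  bases and streaming aggregation (`protocol`, `kernels`);
* the user-side **bandwidth policy**: maximum bandwidth
  `h_max = √γ·l/(2πj)` guaranteeing at least `j` bands with probability
  `1 − C(γ)`, and the rescaling set `{(4n+1)h0}` that keeps bands
  invariant across multi-bandwidth queries, with query refusal;
* the **malicious-server attack**: grid-maxima inference with an
  ε-strength filter, the per-user privacy score
  `Z_i = Σ_j e′_j‖g_j − d_i‖` (expected localization error), and
  single-feature equivalence-class geometry (`adversary`);
* the **GeoInd planar-Laplace baseline** (radius ~ Gamma(2, 1/ε), uniform
  angle) and the 0-feature best-privacy baseline (`geoind`, `adversary`);
* seeded Gaussian-mixture **synthetic populations** with exact densities
  (`mixtures`), and the **privacy–utility sweep** with Spearman utility,
  k-NN bandwidth selection, and gain-per-privacy-cost analysis
  (`evaluation`);
* a CLI (`fedrff simulate / estimate / attack / policy / sweep`) and plain
  text serialization for every artifact (`cli`, `io`).

## Worked example

Twenty thousand users, each revealing only a single cosine projection:

```python
import numpy as np
import fedrff as fr

spec  = fr.builtin_mixture("grid9")          # 9 Gaussians on {-1,0,1}^2
grid  = fr.default_grid("grid9")             # 50x50 grid on [-3,3]^2
pts   = fr.sample_mixture(spec, 20_000, np.random.default_rng(0))

est   = fr.federated_rff_surface(pts, grid, h=0.55, B=1, master_seed=0)
truth = fr.mixture_density(spec, grid)
print("utility (Spearman vs truth):", round(fr.spearman(est, truth), 3))

from fedrff.evaluation import rff_privacy_score, exact_privacy_score
print("privacy Z, RFF B=1 :", round(rff_privacy_score(pts[:500], grid, 0.55, 1, 0), 3))
print("privacy Z, exact KDE:", round(exact_privacy_score(pts[:500], grid, 0.55), 3))
```

Output:

```
utility (Spearman vs truth): 0.968
privacy Z, RFF B=1 : 2.474
privacy Z, exact KDE: 0.047
```

Read: with one feature per user the aggregated surface rank-correlates
0.968 with the true density, while the maxima attack on any individual
response errs by ≈ 2.5 map units on a 6-unit-wide area (the 0-feature
theoretical ceiling is ≈ 2.6) — against 0.047 units (under one grid
spacing, i.e. complete localization) for exact federated KDE.

The same pipeline from the shell:

```bash
fedrff simulate --mixture grid9 --n 20000 --seed 0 --out pts.csv
fedrff estimate --method rff --data pts.csv --mixture grid9 --h 0.55 --b 1 --seed 0 --out surf
fedrff attack   --data pts.csv --method rff --mixture grid9 --h 0.55 --b 1 --seed 0 --out report
fedrff policy   --h0 0.5 --check-h 1.25     # refused: 1.25 is not (4n+1)*0.5
```

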