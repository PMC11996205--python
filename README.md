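# fractaldim

Fractal-dimension estimation for planar movement trajectories.

Animal paths recorded at a constant frame rate (e.g. centroid tracks of
crawling *Drosophila* larvae at 30 fps) are tortuous at some scales and
smooth at others. The fractal dimension *D* quantifies that tortuosity —
*D* = 1 for straight motion, *D* = 2 for space-filling diffusive wander —
and makes movement complexity comparable across animals and genotypes.
This package implements robust estimators of *D* for uniformly
time-sampled planar paths, automatic per-path scale selection, sensitivity
(perturbation) analyses, and a statistical pipeline for comparing groups
of trajectories.

## Methods at a glance

**Box counting.** Cover the plane with half-open boxes of side ε and count
the boxes N(ε) touched by the path; then

    log N(ε) = −D_B · log ε + log C

so *D_B* is the negative slope of an OLS fit of log₁₀ N on log₁₀ ε.
Three counters are provided:

- *original* — count boxes occupied by the sampled points (hash-table,
  O(n)); saturates and biases *D* downward once ε falls below the
  inter-sample spacing;
- *oversampling* — insert S evenly spaced points per segment before
  counting, postponing saturation by a factor ≈ S + 1;
- *exact* — treat the path as a piecewise-linear curve and enumerate every
  box it intersects, by computing each segment's gridline crossings and
  assigning the box of the midpoint between consecutive crossings (plus
  every vertex box). N(ε) then grows like 1/ε at small scales (slope −1),
  the correct limit for a rectifiable curve.

**Temporal sampling.** With constant frame rate, the frame lag δ is a
natural ruler: U(δ) is the mean distance between points δ frames apart on
the non-overlapping downsampled path. If U ∼ C δ^α, the graph-dimension
bound for α-Hölder motion gives

    D_T = 1 + (1 − α) · min(d, 1/α),   which is 1/α for planar α > ½.

U is rotation- and translation-invariant and costs O(n/δ) per lag.

**Scale selection.** *D* is scale-dependent on real paths, and the
informative scale band tracks movement speed. The pipeline normalizes each
path, computes a dense original-counting curve, trims the flat and
saturated tails (count threshold γ = 0.01 by default), and finds the elbow
ε\* by **dual total least squares**: for every two-way split of the
retained scales, fit an orthogonal-distance line to each part and take the
split minimizing the summed squared perpendicular error. Final fits use
scales {3ε\*, 4.5ε\*, 6ε\*} (box methods) or lags δ\*..2δ\* where
δ\* = inf{δ : U(δ) ≥ 3ε\*} (temporal).

**Group comparison.** Shapiro–Wilk on the ANOVA residuals (α = 0.05) gates
the choice between Student's t-test and the two-sided Mann–Whitney U test
for pairwise contrasts against a control group; means are reported with
t-based 95% CIs.

## Worked example

The level-6 Koch curve (4097 vertices, true dimension log 4 / log 3 ≈
1.2619) through the full pipeline:

```python
import fractaldim as fd

koch = fd.generate_koch(6)
for method in ("original", "exact", "temporal"):
    est = fd.estimate_fd(koch, method=method)
    print(f"{method:9s} D = {est.D:.3f}  (r2 = {est.r2:.4f})")
```

```
original  D = 1.318  (r2 = 0.9999)
exact     D = 1.327  (r2 = 0.9999)
temporal  D = 1.321  (r2 = 0.8049)
```

All three estimators land near the true dimension; the pipeline's automatic
elbow (ε\* ≈ 0.0022 here) anchors each fit in the informative scale band.
A direct dyadic-lag fit recovers the dimension to four digits:

```python
import numpy as np

curve = fd.temporal_curve(koch, deltas=2 ** np.arange(7))
alpha, _ = fd.alpha_from_temporal(curve)   # 0.7925
print(1 / alpha)                           # 1.2619
```

Comparing two groups of synthetic larva-like walks (a loosely turning
"mutant" vs a straighter "wild type", 20 paths each):

```python
import numpy as np

def temporal_fd(traj):
    c = fd.temporal_curve(traj, deltas=np.arange(1, 21))
    a, _ = fd.alpha_from_temporal(c)
    return fd.dt_from_alpha(a)

wt  = [temporal_fd(fd.generate_crw(3600, turn_concentration=12.0, seed=i))
       for i in range(20)]
mut = [temporal_fd(fd.generate_crw(3600, turn_concentration=4.0, seed=100 + i)) for i in range(20)]
comp = fd.compare_groups({"wildtype": wt, "mutant": mut}, control="wildtype")
print("test:", comp.test_used)
print("means:", {k: round(v, 3) for k, v in comp.means.items()})
print("p(mutant vs wildtype):", f"{comp.p_values['mutant']:.2e}")
```

```
test: t-test
means: {'wildtype': 1.051, 'mutant': 1.161}
p(mutant vs wildtype): 3.81e-39
```

The looser-turning group is reliably the higher-dimension one.

A CLI mirrors the library (`fd boxcount`, `fd temporal`, `fd elbow`,
`fd perturb`, `fd run`, `fd compare`); trajectories are `frame,x,y` CSV
files and configuration (fps, γ, ξ, presets) comes from YAML/JSON.

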