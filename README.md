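# flowhier

Hierarchical organisation of urban mobility, measured from origin–destination
trip flows.

Cities differ in how trips are organised across their activity landscape:
some route most movement through a nested sequence of activity centers
("onion-like" — think of a dense core ringed by progressively quieter zones),
while in others high-activity hotspots are scattered and trips hop freely
between very different activity levels. `flowhier` quantifies this with a
single nonparametric statistic, the **flow-hierarchy Φ**, computed from any
weighted OD network on spatial cells — mobile-location aggregates, census
commuting tables, phone records — and relates it to per-city indicators such
as modal share, emissions and health outcomes.

## The metric

1. **Hotspot levels (Loubar thresholding).** Sort cells by total outgoing
   trips and build the Lorenz curve of outflows. The tangent at (1, 1) — the
   final-segment slope `s = n·F_max/ΣF` — crosses the x-axis at
   `x* = 1 − 1/s`; cells beyond `x*` are hotspots. Removing them and
   iterating yields ordered levels ℓ = 1…L, from the most active cells down
   to the quietest.

2. **Level-flow matrix.** `T_ij` is the fraction of all inter-cell trips
   that run from level-*i* cells to level-*j* cells (intra-cell trips are
   excluded; `Σ T_ij = 1`).

3. **Flow-hierarchy.** Φ is the tri-diagonal trace of T:

   Φ = Σ_{i=1}^{L−1} (T_ii + T_{i,i+1} + T_{i+1,i}) + T_LL

   Φ = 1 when all flow connects same- or adjacent-level hotspots (tree-like
   organisation); a uniform spread of flow gives the floor
   Φ_u = (3L − 2)/L².

4. **Null models.** Besides Φ_u, a marginal-preserving rewired null
   `T^h_ij = (Σ_k T_ik)(Σ_m T_mj)/(Σ_mk T_mk)` isolates the contribution of
   spatial correlation between hotspot levels from mere heterogeneity of the
   flow distribution. Real (and realistically simulated) cities satisfy
   Φ > Φ_h.

The package also estimates Φ from three production-constrained
trip-distribution models (gravity with configurable mass exponent and
deterrence, radiation, population-weighted opportunities), generates fully
synthetic test cities with a controllable compact-to-sprawled dial, and
provides the correlation machinery (Pearson/Spearman/LOESS explained
variances, nested-OLS variance gain) for linking Φ to urban indicators.

## Worked example

```python
from flowhier import CityConfig, generate_city, city_phi

city = generate_city(CityConfig(seed=1))   # 20x20 km monocentric city
result = city_phi(city)
print(f"phi = {result.phi:.3f}  L = {result.L}  "
      f"phi_u = {result.phi_uniform:.3f}  phi_h = {result.phi_rewired:.3f}")
print("cells per level:", result.level_counts)
```

prints

```
phi = 0.834  L = 6  phi_u = 0.444  phi_h = 0.812
cells per level: [64, 75, 91, 117, 51, 2]
```

The synthetic monocentric city resolves into six hotspot levels; 83% of its
trips run between same- or adjacent-level cells, well above the uniform floor
(0.44) and above the rewired null (0.81) — the excess over Φ_h is the
signature of spatially correlated hotspot placement, here the concentric
ring structure around the core.

The same pipeline runs from the shell:

```bash
flowhier simulate --config city.yaml --out-edges e.csv --out-cells c.csv
flowhier phi --edges e.csv --cells c.csv --out result.json
flowhier hotspots --edges e.csv --cells c.csv --out levels.csv
flowhier correlate --table cities.csv --indicator pt_share --covariates gdp --out stats.json
```

Input formats are plain CSV: edges as `origin,destination,weight`, cells as
`id,x,y[,population]` with projected planar coordinates in km. Every run
writes a `*.manifest.json` with parameters, input digests and the seed,
sufficient to reproduce it exactly.

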