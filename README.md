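# ltcov — laminar thickness covariance of the cortical sheet

The six layers of the isocortex vary in thickness across the cortical
mantle, and regions with similar laminar composition tend to be wired
together. `ltcov` implements the full analysis chain for studying this
organization from per-vertex layer-thickness maps:

- **Laminar thickness covariance (LTC).** Each location's laminar profile
  is the 6-vector of relative layer thicknesses `f = (t_1, …, t_6) / Σt`.
  The LTC between parcels *i* and *j* is the partial correlation of their
  profiles controlling for the cortex-average profile `z̄`,
  `r_ij·z̄ = (r_ij − r_iz̄ r_jz̄) / √((1 − r_iz̄²)(1 − r_jz̄²))`,
  Fisher z-transformed (`arctanh`). The same machinery builds
  microstructural profile covariance (MPC, 50 depth-intensity samples)
  and laminar intensity covariance (LIC, per-layer mean intensities).
- **Principal axes.** Each row of the covariance matrix is sparsified
  (default p = 0.9), a normalized-angle affinity
  `a_ij = 1 − arccos(cos(row_i, row_j))/π` is formed, and PCA (or
  diffusion maps / Laplacian eigenmaps) extracts the gradients; `G1` is
  the principal axis of laminar differentiation.
- **Hierarchy and connectivity.** Asymmetry-based hierarchy from directed
  connectivity, `h_i = Σ_j |A_ij| − Σ_j |A_ji|`; logistic models of
  binary structural-connection likelihood (McFadden pseudo-R²);
  exponential distance models `y = a·e^(−d/λ) + c` and
  distance-residualized covariance.
- **Spatially constrained inference.** Spin permutations of parcel
  centroids on the sphere and variogram-matched surrogate maps, with
  permutation p-values `p = (1 + #extreme) / (n_perm + 1)`.
- **Synthetic cortex.** An icosphere cortex with a planted
  supra-to-infragranular axis, curvature-coupled superficial thinning,
  planted hierarchy, and SC/FC with planted distance and similarity
  effects — so every stage is testable against known ground truth with
  no external atlas.

Mesh preprocessing (disk smoothing on the inflated surface, cotangent
Laplace–Beltrami mean curvature, medoid parcel centroids, graph
geodesics) is included; data travel as GIFTI and CSV.

## Worked example

```python
from scipy.stats import spearmanr
from ltcov import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    output_dir="out",
    simulation=SimulationConfig(seed=1, n_parcels=500),
)
res = run_pipeline(cfg)

emb = res["gradients"]
inc = res["parcellation"].included
rho = spearmanr(emb.gradients_[inc, 0], res["axis_parcel"][inc]).statistic
print(f"G1 explains {emb.explained_variance_ratio_[0]:.1%} of variance")
print(f"Spearman(G1, planted axis) = {rho:.3f}")
print(f"SC ~ LTC pseudo-R2 = {res['sc_fit'].gof:.3f}")
print(f"FC ~ GD decay length = {res['fc_gd_fit'].coefficients['lambda']:.1f} mm")
```

prints (seed 1):

```
G1 explains 35.3% of variance
Spearman(G1, planted axis) = 0.901
SC ~ LTC pseudo-R2 = 0.295
FC ~ GD decay length = 32.8 mm
```

The pipeline excluded the a-/dysgranular pole, smoothed the absolute
layer thicknesses with a 10 mm disk, normalized them to relative
profiles, parcellated by the median, built the Fisher-z partial
correlation matrix, and embedded its principal axis: `G1` reorders the
included parcels along the planted anterior–posterior axis
(ρ = 0.90; 333 of 500 parcels remain after the a-/dysgranular
exclusion), structural-connection likelihood rises with laminar
similarity, and the functional-connectivity distance fit recovers the
planted 30 mm decay length to within 10%. All intermediates (GIFTI maps, CSV matrices,
provenance JSON) are written under `out/`.

A CLI mirrors the library: `ltcov simulate | preprocess | ltc | gradient
| cluster | hierarchy | associate | null | run-all`.

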