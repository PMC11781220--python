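# dftomo — two-stage diffuse fluorescence tomography

`dftomo` reconstructs the three-dimensional distribution of a fluorescent
photosensitizing drug inside strongly scattering tissue from interstitial
continuous-wave measurements, as used for dosimetry in photodynamic therapy
(PDT) of deep-seated tumors such as prostate cancer. A set of *n* bare-tip
optical fibers is placed in the tissue; each fiber in turn delivers
excitation light while the others detect both the transmitted excitation
light and the fluorescence re-emitted by the drug, giving n(n−1)
source–detector pairs.

## Model and method

Light transport is described by the continuous-wave diffusion approximation
(μa ≪ μs′), discretized with linear tetrahedral finite elements and a Robin
boundary condition:

    (K + C + B/2A) Φ = Q,     D = 1/(3 μs′),  μeff = √(μa/D).

Each measurement is a **normalized Born ratio** — fluorescence over
excitation power for the same pair — which cancels source power and fiber
coupling and is *linear* in the unknown nodal fluorescent yield
η(r) = γ μaf(r) (γ: quantum yield, μaf: fluorophore absorption):

    F_{s,d}(η) = Σ_i Gx(r_i, r_s) Gm(r_i, r_d) η_i ΔV_i / Gx(r_d, r_s).

Reconstruction proceeds in two stages:

* **Stage 1 (S1)** — Tikhonov-regularized Levenberg–Marquardt minimization
  of ‖M − F(η)‖² + λ‖L(η − η₀)‖² on a coarse inversion mesh, with
  λ_i = max diag(JᵀJ) · 10^(−i/4) and a 2% relative-residual stopping rule.
  S1 localizes the fluorophore but underestimates it badly (node-averaged
  error ≈ 90%).
* **Stage 2 (S2)** — the S1 image is segmented into a few homogeneous
  regions by adaptive-threshold region growing; the unknowns collapse to
  one value per region (η = T η⁽²⁾, J⁽²⁾ = J T) and are refit by
  unregularized Gauss–Newton. The threshold fractions sweep nine values in
  [0.33, 0.87]; the regionalization with the smallest residual ‖δ‖ wins.
  S2 reduces the node-averaged error to a few percent.

The package also contains the synthetic phantom machinery used to study the
method: spherical and Gaussian-profile inclusions, multiplicative Gaussian
measurement noise, an absolute detection cut-off (Pcut), fiber-position
perturbations, and the standard error metrics (δVi, δμafi, δμafbg, ⟨|e|⟩).

## Worked example

```python
import dftomo

# the default study: a 6.7 mm radius inclusion (mu_af = 0.10 / cm) in a
# 0.01 / cm background, 13 interstitial fibers, mu_a = 0.50, mu_s' = 8.7 / cm
scenario = dftomo.default_scenario(data_mesh_nodes=8000)
result, data = dftomo.simulate_and_reconstruct(
    scenario, fwd_mesh_nodes=8000, recon_mesh_nodes=2000
)
m = result.metrics
print(f"S1 <|e|> = {m.mean_abs_rel_err_s1:.1f}%   S2 <|e|> = {m.mean_abs_rel_err_s2:.1f}%")
print(f"regions = {m.n_regions}  dV = {m.dV_i:+.1f}%  "
      f"d_mu_af_incl = {m.d_mu_af_i:+.1f}%  d_mu_af_bg = {m.d_mu_af_bg:+.1f}%")
```

Output from the run above:

```
S1 <|e|> = 91.7%   S2 <|e|> = 5.4%
regions = 2  dV = +4.2%  d_mu_af_incl = +0.0%  d_mu_af_bg = -4.2%
```

Stage 1 alone misestimates the fluorophore absorption by ~90% on average;
stage 2 finds a two-region partition (inclusion + background), recovers the
inclusion volume and both absorption values within a few percent.

A thin CLI wraps the same pipeline:

```
dftomo simulate    --config scenario.yaml --out-prefix sim
dftomo reconstruct --config scenario.yaml --measurements sim_measurements.csv --out recon.vtk
dftomo evaluate    --gt-vtk sim_mesh.vtk --result-vtk recon.vtk --slice-z 18
dftomo pipeline    --config scenario.yaml
```

Meshes and fields are exchanged as legacy ASCII VTK unstructured grids,
measurements as CSV (`source,detector,excitation_W,fluorescence_W,born_ratio,kept`),
scenarios as YAML.

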