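# speckleflow

Processing pipeline for **coherent spatial imaging**: a compact diffuse-optics
modality that combines **laser speckle contrast imaging (LSI)** with
**spatially resolved diffuse reflectance spectroscopy (srDRS)** to recover
absolute tissue hemodynamics from interleaved multi-wavelength camera frames
— absorption and reduced scattering (μa, μs′), oxy-/deoxy-hemoglobin
concentrations ([HbO2], [Hb], [HbT]), tissue oxygen saturation (StO2), and
blood flow both as the classic uncorrected 1/K² speckleplethysmography (SPG)
index and as the optical-property-corrected Brownian diffusion coefficient
Db.  A synthetic raw-frame simulator with known ground truth stands in for
the hardware, so the whole chain is testable end to end.

Intended users: biomedical-optics researchers prototyping or validating
camera-based srDRS + LSI devices, and anyone needing a tested reference
implementation of lookup-table optical-property inversion and
speckle-visibility flow correction.

## The models at the core

**Diffuse reflectance.** Steady-state diffusion approximation for a
semi-infinite medium with an extrapolated boundary (two-dipole source at
depth z₀ = 1/μt′, image across z_b = 2AD):

R(ρ) = (1/4π) [ z₀ (μ_eff + 1/r₁) e^(−μ_eff r₁)/r₁² + (z₀+2z_b)(μ_eff + 1/r₂) e^(−μ_eff r₂)/r₂² ],
μ_eff = √(3 μa (μa + μs′)).

A lookup table of R(ρ) curves over μa ∈ [0, 0.4] mm⁻¹ and μs′ ∈ [0.3, 3.5]
mm⁻¹ is matched against measured radial profiles (ρ = 3–10 mm) after
phantom-based calibration; all grid nodes fitting with R² above a
per-channel threshold (0.98 for the 660/740 nm LEDs; 0.94 phantom / 0.98
in vivo for the 850 nm VCSEL) and within twice the best node's misfit are
averaged.  An in-repo photon random-walk Monte Carlo with the same boundary
condition serves as an independent transport oracle.

**Flow.** The field autocorrelation under Brownian scatterer motion follows
from the correlation diffusion equation, g₁(ρ,τ) = G(ρ; μa + 2αμs′k₀²D_b τ) / G(ρ; μa),
and the camera-exposure-integrated speckle contrast is

K² = (2β/T) ∫₀ᵀ (1 − τ/T) g₁(ρ,τ)² dτ.

Inverting K(D_b) = K_measured with the concurrently recovered (μa, μs′)
yields the corrected blood-flow index D_b (mm²/s).

**Chromophores.** Scatter-corrected absorption at 660/740/850 nm is
decomposed as μa(λ) = ln10 · (ε_HbO2(λ)[HbO2] + ε_Hb(λ)[Hb]) by least
squares; StO2 = 100·[HbO2]/[HbT].

## Worked example

Simulate a 2 s resting-state scene (ground truth [HbO2] = 50 μM,
[Hb] = 25 μM, D_b = 10⁻⁶ mm²/s), calibrate against a rendered phantom, and
run the full pipeline:

```python
from speckleflow import (PipelineConfig, calibration_from_scene, constant_scene,
                         phantom_scene, render_sequence, run_pipeline)
from speckleflow.srdrs import ProbeGeometry

geom = ProbeGeometry(source_px=(128, 28), pixel_pitch=0.05,
                     rho_min=3.0, rho_max=8.0, bin_width=0.1)
scene = constant_scene(duration=2.0, seed=7, geometry=geom)
seq = render_sequence(scene)                 # 270 interleaved frames @ 135 Hz
cal = calibration_from_scene(phantom_scene(seed=8, geometry=geom))
result = run_pipeline(seq, cal, PipelineConfig(srdrs_window_s=1.0))

row = result.timeseries.iloc[0]
print(f"mua(850) = {row.mua_850:.4f} mm^-1   musp(850) = {row.musp_850:.3f} mm^-1")
print(f"[HbO2] = {row.HbO2_uM:.1f} uM   [Hb] = {row.Hb_uM:.1f} uM   StO2 = {row.StO2_pct:.1f} %")
print(f"SPG (1/K^2) = {row.spg:.1f}   Db = {row.Db:.2e} mm^2/s")
```

prints

```
mua(850) = 0.0150 mm^-1   musp(850) = 1.075 mm^-1
[HbO2] = 44.4 uM   [Hb] = 24.4 uM   StO2 = 64.5 %
SPG (1/K^2) = 15.4   Db = 8.69e-07 mm^2/s
```

The recovered 850 nm absorption sits on the nearest lookup-table node
(truth 0.0162 mm⁻¹, default μa grid step 0.005 mm⁻¹), and that quantization
propagates into the concentration and Db estimates — StO2 lands within ~2
percentage points of the generating 66.7 % and Db within ~15 % of 10⁻⁶
mm²/s.  With a finer grid (or truth on a node) recovery is exact to
round-off; see `docs/methods.md`.

A command-line interface wraps the same chain
(`speckleflow simulate | build-lut | run | cov-report | inspect`):

```bash
speckleflow simulate --protocol venous --seed 1 --out scene.tif --calibration-out cal/
speckleflow run scene.tif --calibration cal/calibration.json --out results/
```

`run` writes `timeseries.csv` (epoch-aligned hemodynamics),
`properties.csv`, `spg_trace.csv` (full-rate SPG) and `report.json`.

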