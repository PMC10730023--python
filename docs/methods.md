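# Methods

This note documents the models, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Light-transport forward model

Diffuse reflectance uses the steady-state diffusion approximation for a
homogeneous semi-infinite medium with an extrapolated boundary: an
isotropic point source at depth z₀ = 1/μt′ (μt′ = μa + μs′) and a negative
image source at z₀ + 2z_b, with z_b = 2AD, D = 1/(3μt′), and the
internal-reflection factor A computed from the refractive index via the
Groenhuis polynomial for the effective diffuse reflection coefficient.
The solution is a closed form, which keeps lookup-table construction
desk-scale; the table builder accepts any callable forward model, so an
externally computed Monte-Carlo table can be dropped in unchanged.

Validity: the model assumes μs′ ≫ μa (a warning is emitted when
μs′ < 10 μa) and separations beyond a transport mean free path.  An
in-repo analog photon random walk (isotropic scattering at μs′, absorption
sampled per interaction, Fresnel reflection at the index-mismatched
surface, pencil-beam launch, unit weight normalized to power entering the
medium) is the independent oracle: at ρ ∈ {3, 5, 8} mm and tissue-like
properties the two agree to within ~11 % (the diffusion model's intrinsic
accuracy at these separations), checked at 10⁷ photons per property pair.

The asymptotic decay slope of ln(ρ²R) converges to −μ_eff =
−√(3μa(μa+μs′)) only deep in the far field; pre-exponential factors
contribute relative corrections of order 1/(ρμ_eff).  The validation
helper therefore fits the slope in the window ρμ_eff ∈ [30, 36], where the
worst-case error across the full property range is ≈1.6 %.  At ρ = 6–10 mm
and μa ≈ 0.01 mm⁻¹ (ρμ_eff ≈ 1–1.7) the local slope is ~25 % shallower
than −μ_eff; that regime is simply pre-asymptotic, not a model defect.

## Radial profiling and calibration

Pixels are binned by Euclidean distance from the source (centre-of-pixel
convention, half-open bins, default width 0.1 mm, ρ ∈ [3, 10] mm by
default).  The reported radial coordinate of a bin is the **mean pixel
distance within the bin**, not the geometric centre: with discrete pixels
and partial annuli the two differ systematically, and using the mean
removes the first-order binning bias identically for sample and phantom.
Dark frames are subtracted first; negative results are clamped to zero;
empty bins are dropped.

The per-separation scale factor is the phantom's theoretical curve (its
known properties snapped to the nearest table node, with a warning beyond
half a grid step) divided by its measured profile.  Any common gain on
sample and phantom cancels exactly.

## Lookup-table inversion

Goodness of fit is the coefficient of determination computed on
**log-reflectance**, R² = 1 − SS_res/SS_tot with SS_tot the theoretical
log-curve's variance about its own mean.  Reflectance spans several
decades over ρ ∈ [3, 10] mm; a linear-space R² is dominated by the
shortest separations (a config flag switches to linear space anyway).

Candidate acceptance combines two rules:

* a fixed per-channel quality floor — R² > 0.98 for the LED channels and
  0.94 (phantom context) / 0.98 (in vivo) for the 850 nm channel;
* a misfit band relative to the best node — R² ≥ 1 − k·(1 − best R²) with
  k = 2 by default.

The floor alone admits a long (μa, μs′) trade-off ridge (log-residual of
~15 % per point still passes at 0.98), whose arithmetic mean is biased by
tens of percent in μs′ even for noiseless curves.  The misfit band scales
the candidate set with the measurement noise instead: a noiseless curve
generated at a grid node is recovered exactly (only the exact node attains
R² = 1), while noisy curves average the several comparably good nodes, in
the spirit of conservative multi-candidate averaging.  Setting
`best_margin_factor=None` restores floor-only acceptance.  When nothing
passes the floor, the single best node is returned with a fallback flag —
never silently.

Measured recovery with the default 81×65 grid and 1 % multiplicative curve
noise: median relative error ≈2 % (μa) and ≈3 % (μs′) over 50 random
off-node pairs, degrading to ≈8 % at 5 % noise.

Grid quantization: the default μa step (0.005 mm⁻¹) is ~30 % of a typical
tissue μa at 850 nm, so off-node truths recover to the nearest node (or a
trade-off pair), and that quantization propagates into concentrations and
Db.  Closure tests therefore place the generating μa values on grid nodes;
the occlusion studies use a finer configured grid (401×129) so that
quantization sits below the physiological step sizes being resolved.  The
LUT is persisted as a self-describing HDF5 container (grids, curves,
validity flags, `model_id`, `schema_version`); property interpolation
between nodes is bilinear in log-reflectance (mid-cell error ≈0.2 %).

## Speckle contrast and SPG

Spatial contrast is K = sample standard deviation (n−1) / mean over a 7×7
window; border pixels lack a full window and are masked rather than
padded.  The SPG trace is 1/(mean K over the ROI)², with the ROI the
annulus ρ ∈ [3.1, 4.4] mm (closed interval) — K is averaged before
squaring for robustness to pixel outliers.

Two deterministic corrections feed the flow inversion (both exposed and
on by default in the pipeline):

* **Flat-field normalization** — the radial mean gradient varies within a
  7×7 window and inflates K; each VCSEL frame is divided by the
  Gaussian-smoothed (σ = 3 px) temporal mean image before contrast
  estimation.  Contrast is scale-invariant, so only the gradient removal
  matters.
* **Window-bias correction** — the sample-CV estimator over n = 49 pixels
  is low by ≈(1 + 3K²)/(4n) (delta method, gamma statistics): −2 % at
  K = 1, −0.6 % at K = 0.25.  The measured ROI contrast is corrected by
  this factor before Db inversion; the SPG trace itself reports the raw
  estimator.

## Flow model and inversion

g₁(ρ,τ) substitutes the dynamic absorption μa + 2αμs′k₀²D_bτ into the
static Green's function and normalizes at τ = 0.  k₀ = 2πn/λ at λ =
850 nm (the coherent channel).  The dynamic fraction α is fixed at 1 and
absorbed into D_b (the two are not separately identifiable), β defaults
to 1 for simulations (estimable from a static phantom as K² at D_b = 0),
and the exposure time defaults to 5 ms (configurable; must be below the
7.4 ms frame period at 135 Hz).

K(D_b) evaluates the visibility integral by adaptive quadrature (absolute
tolerance 10⁻⁹ on K², integration cut where g₁² < 10⁻¹²,
non-convergence raises with diagnostics).  Inversion solves K(D_b) =
K_meas by Brent's method on an expanding bracket (initial [0, 10⁻³]
mm²/s, ×10 up to 10⁻¹; `xtol` = 10⁻¹⁶ so the relative tolerance governs);
round-trip accuracy is ~10⁻¹¹ relative.  K ≥ √β maps to D_b = 0 (static);
K below the model floor at the bracket cap flags non-convergence.  The
reference separation is ρ_ref = 3.75 mm, the midpoint of the SPG ROI.
Property estimates are paired to contrast samples by nearest timestamp
with a 5 s staleness cap (stale samples flagged, not extrapolated).

## Chromophore unmixing

μa(λ) = ln10 · E · c with E the base-10 molar extinction matrix
(mm⁻¹ μM⁻¹) for {HbO2, Hb} at 660/740/850 nm; least-squares solution,
with an optional non-negative mode.  Negative concentrations from noisy
fits are flagged, not clipped.  StO2 is undefined (reported missing) when
[HbT] ≤ 0.1 μM.  The shipped extinction table derives from the standard
OMLC/Prahl compilation (`source_tag` records this); tests synthesize
absorption with the same table, so closure checks are independent of the
compilation choice.  Water and lipid are deliberately excluded from the
basis.

## Synthetic scenes

The generator emulates exactly the physics the pipeline assumes:

* radial mean intensity = gain × diffusion-model R(ρ) + dark offset, with
  optional Poisson shot noise (frames are float64 counts; noiseless LED
  frames carry exact means, noisy ones integer-valued draws);
* VCSEL speckle as i.i.d. gamma marginals with shape 1/K_target², where
  K_target follows the visibility model at the scene's D_b(t) and
  ρ̄ = 3.75 mm — marginal statistics only, no spatial grain correlation
  and no frame-to-frame speckle correlation;
* the 4-frame interleave [VCSEL, 660, VCSEL, 740] at 135 Hz (VCSEL
  67.5 Hz, LEDs 33.75 Hz each), inferred from the printed channel rates;
* a 1 Hz sinusoidal cardiac component (20 % relative amplitude) on D_b.

Baseline ground truth: [HbO2] = 50 μM, [Hb] = 25 μM (StO2 = 66.7 %),
μs′ = 1.2/1.1/1.0 mm⁻¹ at 660/740/850 nm, D_b = 10⁻⁶ mm²/s (a standard
resting-tissue value in correlation-diffusion flowmetry), n = 1.4, frame
256×256 at 0.05 mm/px with the source near one edge.  Absorption time
courses are synthesized from the concentration courses through the same
extinction table the unmixing uses.

Occlusion protocols follow the standard cuff manoeuvres (arterial: 2 min
baseline, 2 min at 220 mmHg, 2 min recovery; venous: 2 min baseline,
1 min each at 20/40/60/80/100 mmHg, 1 min recovery).  The pressure →
hemodynamics response is phenomenological, chosen once for physiological
plausibility and not calibrated: venous occlusion scales [HbT] by
(1 + 0.0025·P) (+25 % at 100 mmHg) and D_b by (1 − 0.0065·P) (−65 % at
100 mmHg, floored at 20 %); arterial occlusion collapses D_b to 5 % of
baseline and converts HbO2 → Hb at 0.15 μM/s at constant [HbT];
transitions relax exponentially with a 2 s time constant.

What passing tests show — and what they do not: the simulator shares the
pipeline's forward models, so end-to-end closure demonstrates the
correctness of the processing chain (calibration cancellation, inversion,
unmixing, flow correction), not the fidelity of the diffusion/visibility
models to real tissue.  Real data add spatially correlated speckle grains,
camera MTF and fixed-pattern noise, probe-tissue coupling drifts, layered
and heterogeneous anatomy, and motion — none of which are emulated.

## Problem sizes in tests and the acceptance script

Long protocols are sampled with 0.4 s full-rate bursts every 15 s (the
hemodynamics of interest evolve over tens of seconds, so burst sampling
preserves every trend while keeping rendering desk-scale); srDRS epochs
equal one burst.  Monte-Carlo validation uses 10⁷ photons per property
pair (4 pairs × 3 separations); noisy-recovery studies use 50 curve
draws / 20 rendered scenes.  The default test geometry trims ρ_max to
8 mm so the full annulus fits the 256-px frame.

## Known limitations

* Absolute agreement with a Monte-Carlo-parameterized lookup table is not
  expected; the calibration scale factor absorbs the absolute offset by
  construction, but curve-shape differences of a few percent remain.
* The discrete-candidate inversion quantizes recovered properties to the
  grid; resolution is a configuration trade-off, not a constant.
* The K → D_b model assumes pure Brownian dynamics, a single coherent
  wavelength, a point-like effective separation ρ_ref, and β known;
  absolute D_b values are model-convention-dependent even though trends
  and ratios are robust.
* Multi-exposure contrast, per-pixel property maps, layered media and
  waveform feature extraction are out of scope.
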