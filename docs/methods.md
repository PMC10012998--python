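# Methods

`cardialt` closes a loop between optical-mapping analysis and tissue-scale
simulation of cardiac alternans: a voltage-sensitive fluorescence movie is
analyzed pixel-wise in the Fourier domain (FFI) and with beat-wise APD maps;
the low-frequency Fourier amplitude ("optical ultrastructure") is normalized
into heterogeneity fields that spatially modulate the parameters of a minimal
ventricular action-potential model on a 2D anisotropic sheet; and the
simulated voltage is analyzed by the *same* FFI/APD code path.  This note
documents the models, the numerical choices, and what the synthetic data do
and do not emulate.

## The membrane model

The four-variable minimal ventricular model evolves a dimensionless membrane
potential `u` (rest 0, peak ≈ 1.5; `u_m = 85.7·u − 84` mV) and three gates
`v, w, s` under three phenomenological currents:

    ∂t u = ∇·(D ∇u) − (J_fi + J_so + J_si)
    J_fi = −Θ(u−θ_v) (u−θ_v)(u_u−u) v / τ_fi        (fast inward)
    J_so = (1−Θ(u−θ_w)) (u−u_o)/τ_o(u) + Θ(u−θ_w)/τ_so(u)   (slow outward)
    J_si = −Θ(u−θ_w) w s / τ_si                      (slow inward)

with Heaviside-switched gate kinetics and tanh-shaped voltage dependence of
`τ_w+`, `τ_w−`, `τ_so` and `s_∞`.  The default constants reproduce canine
endocardial AP shape, conduction velocity and restitution; they are exposed
as a frozen `ModelParameters` dataclass and serialized as flat JSON.
Conventions:

- **Θ(0) = 1** (right-continuous Heaviside), applied uniformly; at a
  threshold voltage the depolarized branch holds.
- The resting state `(u, v, w, s) = (0, 1, 1, s_rest)` with
  `s_rest = (1 + tanh(k_s(0 − u_s)))/2 ≈ 0.021553` is an exact fixed point;
  the 0D integrator preserves it to machine precision.
- Surface-to-volume ratio and membrane capacitance are absorbed into the
  diffusivities; the code works directly in `D` (cm²/ms).

Under pacing, the space-clamped model shows stable 1:1 rhythm down to a
cycle length of ≈ 250 ms and sustained 2:2 APD alternans below ≈ 240 ms
(onset near 4.2–4.5 Hz), with restitution monotone in cycle length.

**Stimulation.** The stimulus is a rectangular current pulse of 2 ms.  The
measured diastolic threshold is ≈ 0.167 /ms for a single cell and ≈ 0.37 /ms
for a 3-pixel edge strip at dx = 0.025 cm (diffusion drains the strip), so
the defaults are set to about twice threshold: 0.33 /ms (0D) and 0.8 /ms
(tissue).  When diffusivity is scaled ×k the strip threshold grows ≈ √k.

## The tissue solver

The monodomain equation is solved on a regular 2D grid with explicit Euler.
The diffusion tensor is built per pixel from a fiber-angle field α(x,y):
`D11 = D∥cos²α + D⊥sin²α`, `D22 = D∥sin²α + D⊥cos²α`,
`D12 = (D∥−D⊥)cosα·sinα`, with defaults D∥ = 0.010, D⊥ = 0.003 cm²/ms
(CV anisotropy ratio √(10/3) ≈ 1.83).

**Phase field.** Irregular tissue shapes use a smooth indicator φ ∈ [0,1]
(Gaussian-smoothed binary mask, σ = 2.5 px, kernel truncated at 2σ, values
below 10⁻³ clipped to 0).  The operator is `(1/φ)∇·(φ D ∇u)` with
`1/max(φ, 10⁻³)`; face diffusivities for the axis terms are harmonic means
of φD, which vanish at the boundary and enforce zero flux on arbitrary
shapes (a rectangular domain with φ ≡ 1 reduces to the classical 5-point
zero-flux stencil, conserving Σu exactly under pure diffusion).  The
`D12` cross terms use centred differences and are dropped on the outermost
grid frame; they vanish anyway for axis-aligned or isotropic fibers.

**Resolutions.** Reference discretization dx = 0.025 cm, dt = 0.01 ms.
Movie-emulation and heterogeneity studies run on 64×64 sheets at
dx = 0.06 cm (the 600 µm optical pixel pitch) with dt = 0.02 ms; the test
suite verifies that halving dx changes CV by < 1% (at common dt) and that
refining dt ×10 changes APD by < 1%.  The explicit stability bound
`dt ≤ dx²/(2(D11+D22) + 4|D12|)` is checked and a warning raised when
violated.  The reaction kernel tabulates the three parameter-independent
tanh shape functions (16384-point linear interpolation, relative error
< 10⁻⁶); the spatially heterogeneous time constants multiply these shapes
exactly, so per-pixel parameter fields lose no accuracy.  A consequence is
that the tissue path holds the resting state only to ~10⁻¹¹ per step
(0D path: < 10⁻¹⁵).

**Pacing-down protocol.** Stages of 10 beats per frequency, frequencies
increasing (cycle length decreasing), voltage recorded every 2 ms; alternans
is assessed on the last two beats of each stage.  Conduction block (less
than half the tissue activated in a stage) is recorded in stage metadata,
not raised.

## FFI analysis

Each pixel trace is discrete-Fourier-transformed over a window (default:
the whole recording, or the recording minus one pacing cycle when the
pacing frequency is supplied); amplitude and phase are recomposed into maps
at the bin nearest a target frequency (bin recorded in metadata).  No
spatial filtering is applied anywhere in the FFI path.  Experimental and
synthetic movies are linearly detrended per pixel before the transform;
simulated membrane potential is not.  Rhythm classification works on peak
tests: a subharmonic line "exists" if it is a local maximum over ±2 bins
with amplitude ≥ 5% of the pacing peak (accepted within ±15% of f_p/2 to
tolerate experimental line splitting, multiplicity reported); a line near
3f_p/4 in addition to f_p/2 marks 4:4; a median off-peak amplitude over
(0.25 f_p, 2 f_p) above 20% of the pacing peak marks fibrillation.  All
phase aggregation uses circular statistics.

The ultrastructure map is |F(0.5 Hz)| on the tissue mask and requires a
window ≥ 2/f_low = 4 s.  The tissue mask itself is SNR-based: peak-to-peak
of the smoothed trace over a MAD noise estimate, threshold 3, largest
connected component, holes filled; isolated above-threshold speckle
(< max(9 px, 0.5%) ) is rejected as noise.

## APD alternans maps

Pre-analysis, in order: per-pixel detrend, 7-frame rectangular moving
average in time, spatial Gaussian smoothing (σ = 2 px truncated at 4 px),
mask-aware so no signal bleeds across the tissue boundary.  Detrending
subtracts a diastolic baseline computed by morphological opening along time
(rolling minimum then maximum over 0.5 s, smoothed) rather than a straight
line: optical baselines wander at sub-Hz frequencies, and under a linear
detrend that wander aliases several milliseconds into ΔAPD.  Movies shorter
than the baseline window fall back to a linear detrend.

APDs are measured at 20% threshold with sub-frame linear interpolation.
Beats are segmented globally (20% of the trace amplitude over the 10th
percentile baseline); each beat's crossings are then re-measured against
per-beat references — the upstroke against the preceding diastolic minimum,
the repolarization against the *following* one — which cancels residual
baseline movement to ≲ 1 ms.  Deflections shorter than 20 ms are discarded
as noise blips.  For maps, beats are indexed ordinally from each pixel's
first detected beat (every pixel sees every paced wave, so parity is
consistent across the tissue); "last2" uses the last two beats complete at
every pixel.  ΔAPDₙ = APDₙ₊₁ − APDₙ; pixels with |ΔAPD| ≤ 2 ms form the
nodal band (the 2 ms matches the frame interval; at coarser sampling the
band scales with the resolution).  Classification: alternating area < 5% of
tissue → `none`; one sign holding ≥ 95% of the alternating area → `CA`;
otherwise `DA`, with connected components, areas and nodal fraction
reported.  CA↔DA transition counting ignores `none` stages.

## Heterogeneity assimilation

The smoothed ultrastructure (Gaussian kernel, radius 6 px, variance 5 px²,
restricted to the mask) is normalized to

    H(x,y) = δ·r/max|r| + 1,    r = s − mean(s over mask),

which has mask-mean exactly 1 and maximal deviation exactly δ ∈ [0,1]
(constant inputs yield H ≡ 1 with a degenerate flag).  The reciprocal field
applies the same normalization to 1/H1 (of the already-normalized H1, per
the direct reading of the procedure; both orders renormalize to mean 1).
Fields multiply parameters pointwise: H1 on `D∥, D⊥`; H2 on the
APD-regulating constants `τ_w1+, τ_w2+, τ_so1, τ_so2, τ_si` (both
sub-constants of each aggregate).  Variants: homogeneous, H1, H2 and H3
(both maps).  Scaled parameters must stay positive; H ≤ 0 anywhere is an
error (only reachable at δ = 1 when the extreme deviation is negative).
Maps resampled between movie and solver grids are bilinear, then
renormalized to mean 1.

Under the pacing-down protocol (3, 5, 6.2 Hz × 10 beats, base pacing,
64×64 sheet at dx = 0.06 cm) the homogeneous model shows no alternans at
3 Hz, concordant alternans at 5 Hz and (CV-restitution-driven) discordant
alternans at 6.2 Hz; the H3 model converts the 5 Hz stage to discordant
alternans with multiple opposite-sign regions, and the alternating-area
fraction at 6.2 Hz is non-decreasing in δ over {0.25, 0.5, 1} for the
reference ultrastructure field; individual random realizations can deviate
by a percent or two around the alternans plateau, where the measure
saturates.  Alternans patterns near onset are strongly history-dependent (direct pacing at a
single rate can land in different alternans bands than the staircase), which
is why the staircase protocol is the standard study here.

## Synthetic data

The generator emulates the acquisition geometry (600 µm pixels, 2 ms
frames) and renders `I = g·(AP(t − delay) + wander) + drift·t + noise`:

- **AP template**: exponential upstroke (τ = 2 ms) times sigmoidal
  repolarization (width 12 ms), numerically calibrated so the
  20%-of-peak duration equals the requested APD to ~0.1 ms; 2:2 rhythms
  alternate `a±d`, 4:4 is the amplitude-modulated cycle
  `a+d₁, a−d₁, a+d₂, a−d₂`; antiphase regions shift the cycle by half a
  period; the alternation amplitude ramps to zero over a 10-pixel (6 mm)
  transition band so the |ΔAPD| ≤ 2 ms nodal line is wider than a pixel, as
  in mapped ventricles.
- **Travel delay**: plane wave from the pacing edge at a configurable CV
  (default 0.05 cm/ms), rounded to the frame interval; movies are rendered
  in the steady pacing regime (the train bank carries a lead-in pad), since
  recordings start mid-pacing and a wave-onset step would otherwise
  dominate the low-frequency spectrum.
- **Baseline wander**: a shared sub-Hz fluctuation (Gaussian-lowpassed
  white noise, ≈ 0.25 s correlation, amplitude 10% of the AP) multiplied by
  the local baseline field `g`.  This is what makes the 0.5 Hz amplitude an
  ultrastructure readout at all — a clean periodic train has no 0.5 Hz
  line; physically it stands for the slow fluorescence fluctuations whose
  size tracks local signal strength.
- **Ultrastructure field** `g`: Gaussian-filtered white noise, mean exactly
  1, coefficient of variation 0.10, autocorrelation half-width 10 px.
- **Noise**: additive Gaussian per pixel-frame, default σ = 2% of the AP
  amplitude; linear drift 1%/s.

Everything is bitwise reproducible given the scene seed.  The generator
does *not* emulate optics (blur, specular reflection), motion, calcium
signals, or cell-scale stochasticity; passing tests demonstrate the
correctness and internal consistency of the analysis and assimilation
chain under controlled conditions, not robustness to every experimental
artifact.

## Closed loop

The closed-loop check imposes a known H2-type heterogeneity (δ = 0.5) on
the APD constants, paces the sheet at 3 Hz for 13 beats (4.33 s, enough to
resolve 0.5 Hz), and re-extracts the ultrastructure from the simulated
voltage with the identical FFI path.  Longer APDs raise the low-frequency
amplitude of a pulse train (duty-cycle effect), so the recovered map
correlates with the imposed field (r ≈ 0.94 ≫ 0.8) even though simulated
voltage has no optical baseline at all.

## Known limitations

- 2D sheets only; no transmural anisotropy, bidomain effects or mechanics.
- Explicit Euler bounds dt ∝ dx²; fine-grid studies get expensive.
- The cross-derivative stencil is non-conservative at the outermost frame;
  with phase-field boundaries the flux there is negligible.
- Rhythm-classification thresholds (5% peak, 20% fibrillation baseline)
  are heuristics calibrated on synthetic spectra; experimental data with
  strong harmonics may need adjusting via the exposed parameters.
- The CA/DA area thresholds (5%, 95%) are conventions; the underlying
  component statistics are always reported alongside the label.
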