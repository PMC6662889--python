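# Methods

## Scope and model

`epikit` simulates two 2-D EPI-family readouts along the phase-encode axis
and everything downstream of them:

* **single-shot EPI** — all `N` phase-encode lines in one echo train, line
  `j` read at `TE + (j − N/2)·Δt` (linear bottom-to-top order, DC on TE);
* **EPIK (EPI with keyhole)** — the central quarter of k-space (the
  *keyhole*) fully sampled every excitation, the periphery split into
  `n = 3` interleaves cycled across shots and completed at reconstruction
  time by a sliding window over the `n` most recent scans.

The shipped presets are the 3 T protocol the package characterizes:
`epi64` (64×64 matrix, Δt = 0.510 ms) and `epik96` (96×96, Δt = 0.890 ms,
keyhole fraction 1/4, 3 interleaves), both with FOV 200 mm, TR/TE
2200/30 ms and grey-matter T2\* = 66 ms.

Only phase-encode timing matters: the readout axis is treated as
instantaneously sampled, and no off-resonance, motion, coil or
parallel-imaging effects are modelled.

## Sampling schedules and echo-time shifting

Each EPIK shot acquires, in k_y order, its bottom-periphery interleave, the
whole keyhole, then its top-periphery interleave, with consecutive echoes
of a segment spaced by the actual echo spacing Δt. Echo-time shifting (ETS)
is implemented as per-shot dead-time adjustments *between* segments: the
interleave of shot `s` is delayed by `(s mod n)·Δt/n`, while the keyhole is
anchored with its DC line on TE in every shot. Two consequences follow:

* the combined peripheral time map of shared multi-shot data increases
  smoothly in k_y at the effective spacing `Δt/n` — the phase-continuity
  requirement ETS exists for;
* every k-space line has a *shot-invariant* acquisition time, so a static
  object yields bit-identical frames, and the keyhole's T2\* weighting does
  not cycle with the shot counter.

The alternative ETS convention (shifting the whole echo train) satisfies
the first property but not the second: it imprints a deterministic ~0.45 %
period-`n` amplitude modulation on the keyhole across frames, which in a
functional time series masquerades as a large artifactual signal (it
dominated temporal SNR and drove residual lag-1 autocorrelation to the
period-3 signature −0.5 in our experiments). Since keyhole contrast
consistency across shots is the design goal of the keyhole method, the
segment-anchored convention is used.

Two per-line timing models are exposed:

* `physical_piecewise` (default) — keyhole lines at Δt spacing, shared
  periphery at Δt/n, DC on TE; this is exactly the per-line schedule above;
* `uniform_effective` — the shot duration spread evenly over all lines
  (0.445 ms/line for `epik96`), the convention behind the sampling-window
  arithmetic `TE ± (N/2)·Δt_eff`: (13.68, 46.32) ms for EPI, (8.64,
  51.36) ms for EPIK, a 10.08 ms wider window; the peripheral update rate
  is `1/(TR·n)` = 1/6.6 s ≈ 0.15 Hz.

Both models span the same readout duration; EPI is the degenerate case
(keyhole fraction 1, one interleave) of the same machinery, bit-for-bit.

## Point-spread function and FWHM

The k-space weight of line `j` is `a_j · exp(−t_j/T2*)`, where `a_j` is the
object signal level of the scan that contributed the line (all 1 in the
stationary case). The PSF is the magnitude of the zero-padded DFT of that
weight profile on an axis of `N × oversample` points spanning one FOV in
normalized units [−0.5, 0.5), peak-normalized to 1 (oversample default 64;
grid error far below the 4th decimal reported).

FWHM is measured between the half-maximum crossings bracketing the peak,
located by linear interpolation. Two measurement grids exist, and the
distinction matters at these line counts:

* `image` (default) — crossings interpolated between samples at native
  image-pixel spacing: the resolution actually realized on the
  reconstructed grid. This convention reproduces the protocol's
  characterization: EPI 0.01696 (3.39 mm at FOV 200 mm), EPIK 0.01200
  (2.40 mm) with piecewise timing — a ~41 % resolution advantage for the
  keyhole readout.
* `fine` — all oversampled samples; converges to the continuous profile
  (Dirichlet-kernel limits 1.206/N magnitude, 0.886/N intensity for
  uniform weights), used by the analytic-oracle tests.

A `magnitude`/`intensity` (squared-magnitude) convention flag is provided;
`magnitude` is the default used throughout.

### Dynamic (BOLD) case

The worst-case dynamic scenario modulates the three scans sharing one
k-space by a linear 5 % ramp (1.000, 1.025, 1.050) — the typical 3 T
block-design amplitude compressed into one sliding window. The analyzed
volume is the one whose keyhole was acquired at baseline, with the shared
periphery spanning the rise; interleave `i` carries amplitude `a_i`. The
period-3 peripheral modulation aliases to coherent side peaks at exactly
±1/3 FOV — positions where the stationary profile has a near-null — with
relative magnitude 0.0068, and perturbs the image-grid FWHM by +0.15 %.
`modulation_ghosts` measures the profile at the ±k/n harmonics (optionally
as excess over a stationary reference); `side_peaks` lists generic local
maxima, whose leading entries are ordinary Dirichlet sidelobes an order of
magnitude above the ghost — the reason ghosts are measured at their known
positions rather than by peak-picking.

## Forward model and reconstruction

`synthesize_shot` samples each scheduled line as the corresponding row of
the 2-D DFT of the object *as it exists at that line's acquisition time*
(per-TR evaluation available for slowly varying objects), scales it by
`exp(−t/T2*)`, and adds circularly-symmetric complex Gaussian noise per
acquired line. Noise streams are keyed by `(seed, scan_index)`, so the
peripheral noise a sliding window reuses is genuinely shared between the
frames that reuse it — the mechanism behind the keyhole scheme's temporal
correlation behaviour. Array conventions are frozen: (phase-encode,
readout) axes, DC at index `N/2`, `fftshift(fft2(ifftshift(·)))` forward.

Reconstruction fills each scan's grid from the sliding-window source map
(keyhole from the current scan, each peripheral line from the most recent
covering scan) and inverts by 2-D FFT; magnitudes are kept. The first
`n − 1` scans are not reconstructable and the first two scans are dropped
as dummies (`drop_first = 2`), mirroring a steady-state discard: 225
acquired scans yield 223 frames for either readout.

## Synthetic phantom and paradigm

The phantom is a layered elliptical object (tissue 1.0 on background 0,
an off-centre darker inner ellipse) with two disjoint disc ROIs ("motor",
"visual") 10 % brighter than tissue. The paradigm is 20 s fixation then 7
cycles of 32 s task / 32 s rest (468 s, fitting the 495 s of 225 × 2.2 s
scans); ROI intensity follows the paradigm boxcar convolved with a
canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s,
dispersions 1 s, peak:undershoot 6, unit-area normalized so a sustained
block plateaus at the nominal amplitude, default 5 %). Block boundaries
may optionally be snapped to the TR grid (32 s is not a multiple of
2.2 s); the generative path and the GLM design share one code path, so
paradigm discretization cancels in recovery tests.

What the phantom deliberately lacks: anatomy, physiological noise spectra,
motion, multi-slice geometry, geometric distortion. Passing tests
therefore demonstrate the *mechanics* of the sampling schemes (resolution,
ghosting, sharing-induced correlation, susceptibility attenuation
ordering), not in vivo effect sizes.

## Susceptibility dropout

Local susceptibility gradients shift the effective echo time:
`Q = 1 − γ·Δt/(2π)·FOV·G_SP`, `TE′ = TE/Q`, with γ the proton
gyromagnetic ratio (2.675×10⁸ rad s⁻¹ T⁻¹), Δt the (effective) echo
spacing and G_SP in mT/m. Pixels are attenuated by
`exp(−(TE′−TE)/T2*)`; `Q ≤ 0` is the signal-void regime and is zeroed.
Because TE′ grows with Δt at fixed positive G_SP, the keyhole readout
(0.445 ms effective) retains at least as much signal as EPI (0.510 ms)
in every positive-gradient pixel. Only this attenuation mechanism is
modelled — no geometric warping.

## Functional metrics

Pixelwise OLS against [constant, unit-plateau task response, its temporal
derivative, linear drift]; percent signal change is `100·β_task/β_const`;
ROI statistics come from the same fit applied to ROI-mean series. tSNR is
temporal mean over SD (zero-variance pixels flagged infinite and excluded
from summaries). Residual autocorrelation is the standard lag-k sample
coefficient of ROI-mean residuals (max lag 5), judged against the
±1.96/√n white-noise band. The periphery sharing couples only high
spatial frequencies, so block-mean ROIs — which are spatially low-pass —
show little of it; the test suite uses scattered-pixel ROIs where the
effect is visible, and bounds it by the peripheral noise-variance
fraction.

## Problem sizes and numerical choices

Default simulations in the test suite run at 32–64 pixel grids and 24–64
scans with a compressed paradigm (8.8 s fixation, 2 × 22 s blocks), sizes
chosen so the whole suite, including the 200-replicate type-I-error check
and 50-replicate amplitude-recovery check, completes in well under a
minute; the acceptance script runs the full 225-scan, 64/96-matrix
protocol. Tolerances: FWHM reported to 4 decimals (oversampled grid error
≪ 10⁻⁴), sliding-window-vs-direct agreement asserted at 10⁻¹⁰ relative,
OLS residual orthogonality at accumulated float tolerance. Ties and
degenerate inputs: flat profiles (single line) have no measurable FWHM and
are reported NaN; `Q = 0` is treated as void; constant residual series are
rejected rather than yielding 0/0.

## Known limitations

* 1-D PSF treatment (phase-encode axis only); no 2-D PSF or off-resonance
  distortion.
* The dynamic-PSF scenario fixes which scan's keyhole anchors the shared
  window (the baseline scan); other choices change the sub-percent FWHM
  perturbation but not the ghost structure.
* Susceptibility acts as static attenuation; real dropout includes
  distortion and through-plane dephasing.
* tSNR magnitudes reflect the synthetic noise model (thermal-like k-space
  noise only) and are not comparable to in vivo values, which are
  physiological-noise dominated.
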