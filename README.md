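# epikit

Simulation and desk-scale analysis of **EPI with keyhole (EPIK)** k-space
sampling for fMRI, side by side with standard single-shot EPI.

Single-shot EPI reads all phase-encode lines of k-space in one echo train;
the train's length sets both the T2\*-decay blur (point-spread-function
width) and the vulnerability to susceptibility-induced signal dropout.
EPIK fully samples the central band of k-space (the *keyhole*, here 1/4 of
the lines) on every excitation while cycling the periphery over three
interleaves, completing each scan's k-space by a sliding window over the
three most recent shots. Each shot therefore reads half the lines of a
comparable EPI train, yet one image is produced per TR. This package
implements, for users who want to reason quantitatively about such
readouts without a scanner:

* per-shot phase-encode **schedules** with echo-time shifting, sampling
  windows, update rates, and sliding-window source maps
  (`epikit.trajectory`);
* T2\*-decay-weighted **point-spread functions**, FWHM in FOV-normalized
  and mm units, and view-sharing ghost metrics for dynamic (BOLD-like)
  signals (`epikit.psf`);
* a line-by-line **forward model and sliding-window reconstruction** for
  time-varying digital phantoms, with shared per-line noise
  (`epikit.recon`);
* a **block-design BOLD phantom** (canonical double-gamma HRF, 5 %
  amplitude) and a susceptibility-dropout model
  `Q = 1 − γΔt/(2π)·FOV·G_SP`, `TE′ = TE/Q` (`epikit.phantom`);
* **functional metrics** — tSNR, GLM activation and percent signal
  change, residual autocorrelation — and scheme comparisons
  (`epikit.analysis`);
* a CLI: `epikit psf | simulate | report`.

The central resolution result: with T2\* = 66 ms, TE 30 ms, FOV 200 mm,
the magnitude PSF measured on the reconstructed image grid has FWHM
0.0170 of the FOV (3.39 mm) for 64-line EPI at 0.510 ms echo spacing, but
0.0120 (2.40 mm) for 96-line EPIK at 0.890 ms actual / 0.445 ms effective
spacing — about 41 % sharper. A worst-case 5 % signal swing across the
three shots sharing one k-space adds only symmetric ghosts of relative
magnitude 0.0068 at ±FOV/3 and perturbs the FWHM by ~0.15 %.

## Worked example

```bash
epikit psf --preset epik96 --out out/
```

prints the stationary PSF metrics of the 96-matrix keyhole readout

```json
{
  "scheme": "EPIK",
  "timing_model": "physical_piecewise",
  "convention": "magnitude",
  "mode": "stationary",
  "fwhm_norm": 0.012003434180290696,
  "fwhm_mm": 2.400686836058139
}
```

i.e. a 2.40 mm full width at half maximum at 200 mm FOV — the
T2\*-decay-limited resolution on the image grid. After also running
`epikit psf --preset epi64 --out out/` and the dynamic case
(`--mode dynamic --ramp 0.05`), a consolidated table with pass/fail
against the configured tolerances is produced by `epikit report --out out/`:

```text
preset                  quantity     value  reference  tolerance status
 epi64              window_lo_ms 13.680000    13.6800     0.0050   pass
 epi64              window_hi_ms 46.320000    46.3200     0.0050   pass
 epi64                 fwhm_norm  0.016956     0.0170     0.0005   pass
 epi64                   fwhm_mm  3.391203     3.4000     0.0500   pass
epik96              window_lo_ms  8.640000     8.6400     0.0050   pass
epik96              window_hi_ms 51.360000    51.3600     0.0050   pass
epik96      window_width_diff_ms 10.080000    10.0800     0.0050   pass
epik96 effective_echo_spacing_ms  0.445000     0.4450     0.0050   pass
epik96  periphery_update_rate_hz  0.151515     0.1500     0.0050   pass
epik96                 fwhm_norm  0.012003     0.0121     0.0005   pass
epik96                   fwhm_mm  2.400687     2.4100     0.0500   pass
epik96                 ghost_mag  0.006834     0.0068     0.0015   pass
```

The rows read: EPI's effective sampling window runs 13.68–46.32 ms after
excitation and EPIK's 8.64–51.36 ms (10.08 ms wider, hence more tolerant
of local susceptibility gradients at matched TE), EPIK's periphery
refreshes at 1/6.6 s ≈ 0.15 Hz — far above block-design haemodynamic
rates — and the FWHM/ghost values are as discussed above.

An end-to-end synthetic fMRI comparison (phantom → shots → sliding-window
reconstruction → GLM) is run with

```bash
epikit simulate --schemes epi,epik --scans 225 --seed 1 --out out/
```

which writes NIfTI series, per-scheme metrics CSVs and a comparison table
(recovered ~5 % amplitude on both arms, comparable tSNR, and a small
positive sharing-induced lag-1 residual autocorrelation on the EPIK arm).

From Python, the same objects are available directly:

```python
import epikit as ek

p = ek.get_preset("epik96")
profile = ek.compute_psf(ek.decay_trajectory(ek.effective_line_times(p)))
print(profile.fwhm_norm, profile.fwhm_mm)   # 0.01200... 2.4006...
```

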