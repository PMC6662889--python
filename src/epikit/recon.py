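"""Forward k-space synthesis and sliding-window image reconstruction.

The forward model samples, for every scheduled phase-encode line, the
corresponding row of the 2-D discrete Fourier transform of the object as it
exists at that line's acquisition time, applies ``exp(-t/T2*)`` decay, and
adds circularly-symmetric complex Gaussian noise per acquired line (so
peripheral noise reused by the sliding window is genuinely shared between
the frames that reuse it).  Reconstruction fills each scan's k-space from
its :func:`~epikit.trajectory.sliding_window_sources` map and inverts with
a 2-D FFT; magnitude images are returned.

Array conventions (frozen): axes are (phase-encode, readout); the DC
coefficient sits at index ``matrix // 2`` on both axes; image -> k-space is
``fftshift(fft2(ifftshift(img)))``.  The readout axis is treated as
instantaneously sampled — only phase-encode timing matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence

import numpy as np

from .trajectory import (
    SamplingSchedule,
    Scheme,
    SequenceParams,
    make_schedule,
    sliding_window_sources,
)

__all__ = [
    "ShotFrame",
    "VolumeSeries",
    "image_to_kspace",
    "kspace_to_image",
    "synthesize_shot",
    "synthesize_series",
    "assemble_kspace",
    "recon_image",
    "recon_series",
    "write_nifti",
]


@dataclass(frozen=True)
class ShotFrame:
    """k-space rows measured by one excitation."""

    scan_index: int
    lines: Dict[int, np.ndarray]
    schedule: SamplingSchedule = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.lines) != set(self.schedule.line_indices):
            raise ValueError("populated lines do not match the schedule")


@dataclass
class VolumeSeries:
    """Magnitude image time series, one frame per reconstructed scan."""

    frames: np.ndarray  # (n_frames, matrix_py, matrix_ro)
    tr_ms: float
    first_scan_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (scan_index * TR)."""
        idx = self.first_scan_index + np.arange(self.n_frames)
        return idx * self.tr_ms / 1000.0


def image_to_kspace(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))


def kspace_to_image(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k)))


def synthesize_shot(
    phantom_state_fn: Callable[[float], np.ndarray],
    schedule: SamplingSchedule,
    noise_sd: float = 0.0,
    seed: int | None = None,
    per_line_dynamics: bool = True,
) -> ShotFrame:
    """Measure one excitation's k-space rows from a time-varying object.

    ``phantom_state_fn(t_ms)`` returns the 2-D object at absolute time
    ``t_ms``; line times are ``scan_index * TR + acq_time``.  With
    ``per_line_dynamics=False`` the object is evaluated once per shot (at
    the echo time) — appropriate when the object varies slowly relative to
    the readout.  Decay uses the schedule's ``params.t2star_ms``; noise is
    i.i.d. circular complex Gaussian per sample, reproducible under ``seed``
    (streams are keyed by (seed, scan_index) so shots are independent).
    """
    params = schedule.params
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(
        None if seed is None else [int(seed), schedule.shot_index]
    )
    t_shot = schedule.shot_index * params.tr_ms
    t2 = params.t2star_ms

    lines: Dict[int, np.ndarray] = {}
    if not per_line_dynamics:
        img = phantom_state_fn(t_shot + params.te_ms)
        _check_shape(img, params)
        k_full = image_to_kspace(img)
    for entry in schedule.entries:
        if per_line_dynamics:
            img = phantom_state_fn(t_shot + entry.acq_time_ms)
            _check_shape(img, params)
            row = image_to_kspace(img)[entry.line_index].copy()
        else:
            row = k_full[entry.line_index].copy()
        if math.isfinite(t2):
            row *= math.exp(-entry.acq_time_ms / t2)
        if noise_sd > 0:
            row += noise_sd * (
                rng.standard_normal(row.size) + 1j * rng.standard_normal(row.size)
            )
        lines[entry.line_index] = row
    return ShotFrame(schedule.shot_index, lines, schedule)


def _check_shape(img: np.ndarray, params: SequenceParams) -> None:
    if img.shape != (params.matrix_py, params.matrix_ro):
        raise ValueError(
            f"phantom shape {img.shape} does not match matrix "
            f"({params.matrix_py}, {params.matrix_ro})"
        )


def synthesize_series(
    phantom_state_fn: Callable[[float], np.ndarray],
    params: SequenceParams,
    n_scans: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    per_line_dynamics: bool = False,
) -> List[ShotFrame]:
    """All shots of an experiment (one schedule per scan index)."""
    return [
        synthesize_shot(
            phantom_state_fn,
            make_schedule(params, s),
            noise_sd=noise_sd,
            seed=seed,
            per_line_dynamics=per_line_dynamics,
        )
        for s in range(n_scans)
    ]


def assemble_kspace(
    shots: Sequence[ShotFrame], scan_index: int, params: SequenceParams
) -> np.ndarray:
    """Complete k-space for one scan via the sliding-window source map."""
    by_scan = {s.scan_index: s for s in shots}
    sources = sliding_window_sources(scan_index, params)
    k = np.empty((params.matrix_py, params.matrix_ro), complex)
    for line, src in sources.items():
        if src not in by_scan:
            raise ValueError(f"missing source shot {src} for line {line}")
        try:
            k[line] = by_scan[src].lines[line]
        except KeyError:
            raise ValueError(
                f"source shot {src} did not acquire line {line}"
            ) from None
    return k


def recon_image(kspace: np.ndarray) -> np.ndarray:
    """Magnitude of the inverse 2-D DFT of a fully assembled grid."""
    k = np.asarray(kspace)
    if np.isnan(k).any():
        raise ValueError("k-space grid contains unassembled (NaN) entries")
    return np.abs(kspace_to_image(k))


def recon_series(
    shots: Sequence[ShotFrame],
    params: SequenceParams,
    drop_first: int = 2,
) -> VolumeSeries:
    """Reconstruct every scan from the first usable index onward.

    The first ``n_interleaves - 1`` scans lack a complete sliding window and
    are never reconstructable; ``drop_first`` additionally mirrors dummy
    scans discarded before steady state.  The first retained frame has scan
    index ``max(drop_first, n_interleaves - 1)``.
    """
    shots = list(shots)
    if len(shots) < params.n_interleaves:
        raise ValueError("need at least n_interleaves shots")
    first = max(drop_first, params.n_interleaves - 1)
    frames = [
        recon_image(assemble_kspace(shots, s, params))
        for s in range(first, len(shots))
    ]
    return VolumeSeries(np.stack(frames), params.tr_ms, first_scan_index=first)


def write_nifti(series: VolumeSeries, path, fov_mm: float | None = None) -> None:
    """Write the series as a single-slice 4-D NIfTI (x, y, 1, t); the TR is
    recorded in the header's 4th zoom (seconds)."""
    import nibabel as nib

    ny, nx = series.frames.shape[1:]
    data = np.transpose(series.frames, (2, 1, 0))[:, :, np.newaxis, :]
    vox = (fov_mm / ny) if fov_mm else 1.0
    affine = np.diag([vox, vox, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((vox, vox, 1.0, series.tr_ms / 1000.0))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
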