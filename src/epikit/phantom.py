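"""Synthetic objects, block-design BOLD modulation, and susceptibility dropout.

The phantom is a layered elliptical object with disc-shaped "activated"
regions whose intensity follows a block paradigm (20 s fixation, then 7
cycles of 32 s task / 32 s rest) convolved with a canonical double-gamma
haemodynamic response function, at a plateau amplitude of 5% — the typical
BOLD signal change at 3 T.

Susceptibility-induced dropout is modelled through the effective echo time

    Q   = 1 - gamma * dt / (2 pi) * FOV * G_SP
    TE' = TE / Q

where ``gamma`` is the proton gyromagnetic ratio (rad s^-1 T^-1), ``dt``
the echo spacing, FOV the field of view and ``G_SP`` the local
susceptibility gradient.  Positive ``G_SP`` lengthens TE' and attenuates
the signal by ``exp(-TE'/T2*) / exp(-TE/T2*)``; ``Q <= 0`` is the
signal-void regime (the echo is pushed out of the sampling window).  A
shorter echo spacing — EPIK's effective 0.445 ms versus EPI's 0.510 ms —
gives a smaller TE' shift and therefore less dropout.  Geometric distortion
is intentionally not modelled, only the attenuation mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import stats

from .trajectory import SequenceParams

__all__ = [
    "GAMMA_PROTON_RAD_PER_S_PER_T",
    "Paradigm",
    "PhantomSpec",
    "SusceptibilityModel",
    "Phantom",
    "make_phantom",
    "canonical_hrf",
    "boxcar",
    "bold_timecourse",
    "effective_te",
    "apply_susceptibility",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON_RAD_PER_S_PER_T = 2.675221874e8

#: canonical double-gamma HRF constants (seconds): response peak delay 6,
#: undershoot delay 16, dispersions 1, peak:undershoot ratio 6
HRF_PEAK_DELAY_S = 6.0
HRF_UNDER_DELAY_S = 16.0
HRF_PEAK_DISP_S = 1.0
HRF_UNDER_DISP_S = 1.0
HRF_RATIO = 6.0


@dataclass(frozen=True)
class Paradigm:
    """Block design: ``fixation_s`` of rest, then ``n_cycles`` of
    [``block_s`` task, ``block_s`` rest]."""

    fixation_s: float = 20.0
    block_s: float = 32.0
    n_cycles: int = 7

    def __post_init__(self) -> None:
        if self.fixation_s < 0 or self.block_s <= 0 or self.n_cycles < 1:
            raise ValueError("paradigm durations must be positive")

    @property
    def duration_s(self) -> float:
        return self.fixation_s + 2 * self.block_s * self.n_cycles

    def onsets_durations(self) -> list[Tuple[float, float]]:
        """FSL-style (onset, duration) pairs of the task blocks, seconds."""
        return [
            (self.fixation_s + 2 * self.block_s * c, self.block_s)
            for c in range(self.n_cycles)
        ]


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of the synthetic object and its dynamics."""

    shape: Tuple[int, int] = (96, 96)
    background: float = 0.0
    tissue: float = 1.0
    roi_amplitudes: Dict[str, float] = field(
        default_factory=lambda: {"motor": 0.05, "visual": 0.05}
    )
    paradigm: Paradigm = field(default_factory=Paradigm)
    tr_ms: float = 2200.0
    noise_sd: float = 0.0
    seed: int = 0
    g_sp_mt_per_m: np.ndarray | float = 0.0  # per-pixel susceptibility gradient

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.roi_amplitudes.values()):
            raise ValueError("ROI amplitudes must be >= 0")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")


@dataclass(frozen=True)
class SusceptibilityModel:
    """Attenuation-free scaling Q and effective echo time TE' = TE/Q."""

    delta_t_ms: float
    fov_mm: float
    g_sp_mt_per_m: float | np.ndarray
    gamma: float = GAMMA_PROTON_RAD_PER_S_PER_T

    @property
    def q(self) -> float | np.ndarray:
        return 1.0 - (
            self.gamma
            * (self.delta_t_ms * 1e-3)
            / (2.0 * np.pi)
            * (self.fov_mm * 1e-3)
            * (np.asarray(self.g_sp_mt_per_m, float) * 1e-3)
        )


def _disc(shape: Tuple[int, int], center: Tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _ellipse(shape, center, semi) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - center[0]) / semi[0]) ** 2 + ((xx - center[1]) / semi[1]) ** 2 <= 1.0


@dataclass
class Phantom:
    """Baseline image, ROI masks, and the time-varying object."""

    spec: PhantomSpec
    baseline: np.ndarray
    roi_masks: Dict[str, np.ndarray]

    def state(self, t_ms: float) -> np.ndarray:
        """Object at absolute time ``t_ms`` (BOLD modulation applied)."""
        img = self.baseline.copy()
        factors = bold_timecourse(self.spec, t_ms)
        for name, mask in self.roi_masks.items():
            img[mask] *= factors[name]
        return img


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministic structured object: a large tissue ellipse with an
    off-centre inner ellipse of lower intensity, plus disjoint disc ROIs.

    ROI placement scales with the grid; masks are returned for analysis.
    Raises if the configured ROIs overlap.
    """
    ny, nx = spec.shape
    img = np.full(spec.shape, spec.background, float)
    img[_ellipse(spec.shape, (ny / 2, nx / 2), (0.42 * ny, 0.38 * nx))] = spec.tissue
    img[_ellipse(spec.shape, (0.40 * ny, 0.52 * nx), (0.16 * ny, 0.12 * nx))] *= 0.7

    centers = {
        "motor": (0.30 * ny, 0.30 * nx),
        "visual": (0.72 * ny, 0.55 * nx),
    }
    radius = 0.07 * min(ny, nx)
    masks: Dict[str, np.ndarray] = {}
    for name in spec.roi_amplitudes:
        c = centers.get(name)
        if c is None:
            # extra ROIs fan out along the midline
            c = (0.5 * ny, (0.2 + 0.2 * len(masks)) * nx)
        masks[name] = _disc(spec.shape, c, radius)
        img[masks[name]] = spec.tissue * 1.1  # ROIs slightly brighter than tissue

    total = np.zeros(spec.shape, int)
    for m in masks.values():
        total += m
    if (total > 1).any():
        raise ValueError("ROI masks overlap")
    return Phantom(spec, img, masks)


def canonical_hrf(t_s: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``t_s`` (seconds), normalized
    to unit area so that a sustained unit input plateaus at 1."""
    t = np.asarray(t_s, float)
    h = stats.gamma.pdf(t, HRF_PEAK_DELAY_S / HRF_PEAK_DISP_S, scale=HRF_PEAK_DISP_S)
    h = h - stats.gamma.pdf(
        t, HRF_UNDER_DELAY_S / HRF_UNDER_DISP_S, scale=HRF_UNDER_DISP_S
    ) / HRF_RATIO
    area = 1.0 - 1.0 / HRF_RATIO  # analytic integral of the two gamma pdfs
    return h / area


def boxcar(paradigm: Paradigm, t_s: np.ndarray, snap_tr_s: float | None = None) -> np.ndarray:
    """Task indicator at times ``t_s`` (seconds).  With ``snap_tr_s`` the
    block boundaries are rounded to the nearest multiple of the TR (32 s is
    not an integer multiple of 2.2 s)."""
    t = np.asarray(t_s, float)
    out = np.zeros_like(t)
    for onset, dur in paradigm.onsets_durations():
        if snap_tr_s:
            onset = round(onset / snap_tr_s) * snap_tr_s
            dur = round(dur / snap_tr_s) * snap_tr_s
        out[(t >= onset) & (t < onset + dur)] = 1.0
    return out


_HRF_GRID_DT_S = 0.1


def _convolved_response(paradigm: Paradigm, pad_s: float = 40.0):
    """HRF-convolved boxcar on a fine grid (cached per paradigm)."""
    key = (paradigm.fixation_s, paradigm.block_s, paradigm.n_cycles, pad_s)
    cached = _convolved_cache.get(key)
    if cached is not None:
        return cached
    t = np.arange(0.0, paradigm.duration_s + pad_s, _HRF_GRID_DT_S)
    box = boxcar(paradigm, t)
    h = canonical_hrf(np.arange(0.0, 32.0, _HRF_GRID_DT_S))
    resp = np.convolve(box, h)[: t.size] * _HRF_GRID_DT_S
    _convolved_cache[key] = (t, resp)
    return t, resp


_convolved_cache: dict = {}


def bold_timecourse(spec: PhantomSpec, t_ms: float) -> Dict[str, float]:
    """Multiplicative BOLD factor of each ROI at absolute time ``t_ms``.

    The factor is ``1 + amplitude * r(t)`` where ``r`` is the paradigm
    boxcar convolved with the canonical HRF (unit plateau); it is 1 during
    the initial fixation and outside ROIs.
    """
    if t_ms < 0:
        raise ValueError("time must be non-negative")
    grid_t, resp = _convolved_response(spec.paradigm)
    r = float(np.interp(t_ms / 1000.0, grid_t, resp))
    return {name: 1.0 + amp * r for name, amp in spec.roi_amplitudes.items()}


def effective_te(
    model: SusceptibilityModel, te_ms: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Effective echo time TE' = TE / Q and the void-regime flag.

    Returns ``(te_prime_ms, void)`` with ``void = Q <= 0`` (echo pushed out
    of the sampling window; TE' is NaN there).  For positive G_SP, TE' > TE,
    and TE' grows with the echo spacing at fixed G_SP.
    """
    q = np.asarray(model.q, float)
    void = q <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        te_prime = np.where(void, np.nan, te_ms / np.where(void, np.nan, q))
    if np.isscalar(model.g_sp_mt_per_m) and q.ndim == 0:
        return float(te_prime), bool(void)
    return te_prime, void


def apply_susceptibility(
    baseline: np.ndarray,
    g_sp_map_mt_per_m: np.ndarray,
    params: SequenceParams,
    use_effective_spacing: bool = True,
) -> np.ndarray:
    """Attenuate an image by local susceptibility gradients.

    Each pixel is scaled by ``exp(-TE'/T2*) / exp(-TE/T2*)`` with TE'
    computed pixelwise from the sequence's (effective) echo spacing;
    void-regime pixels (Q <= 0) are zeroed.
    """
    g = np.asarray(g_sp_map_mt_per_m, float)
    if g.shape != baseline.shape:
        raise ValueError("G_SP map shape does not match the image")
    dt = (
        params.effective_echo_spacing_ms
        if use_effective_spacing
        else params.echo_spacing_ms
    )
    model = SusceptibilityModel(dt, params.fov_mm, g)
    te_prime, void = effective_te(model, params.te_ms)
    atten = np.exp(-(te_prime - params.te_ms) / params.t2star_ms)
    atten = np.where(void, 0.0, atten)
    return baseline * atten
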