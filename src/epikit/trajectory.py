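"""Phase-encode sampling schedules for single-shot EPI and EPIK.

EPIK (EPI with keyhole) fully samples a central band of k-space (the
"keyhole") on every excitation while the periphery is acquired as one
interleave of an ``n_interleaves``-shot segmentation.  A sliding-window
reconstruction completes each scan's k-space by borrowing the peripheral
interleaves of neighbouring scans, so one image is produced per TR, as in
single-shot EPI, while each shot reads only half the lines.

This module generates those per-shot line orderings together with the time
(after excitation) at which each line is read, applies echo-time shifting
(ETS) so that shared multi-shot data carry a smoothly increasing phase, and
exposes the sampling-window / update-rate arithmetic that characterizes the
two readouts.  Line index 0 is the most negative k_y; the DC line sits at
``matrix_py // 2`` and is always acquired at the nominal echo time TE
(for the reference shot, offset 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Tuple

import pandas as pd

__all__ = [
    "Scheme",
    "TimingModel",
    "Region",
    "SequenceParams",
    "ScheduleEntry",
    "SamplingSchedule",
    "EffectiveTimeMap",
    "make_epi_schedule",
    "make_epik_schedule",
    "make_schedule",
    "effective_line_times",
    "sampling_window",
    "periphery_update_rate",
    "sliding_window_sources",
    "keyhole_bounds",
    "schedule_to_frame",
]


class Scheme(str, Enum):
    EPI = "EPI"
    EPIK = "EPIK"


class TimingModel(str, Enum):
    """How acquisition times are assigned to reconstructed k-space lines.

    ``uniform_effective`` spreads the shot duration evenly over all
    ``matrix_py`` lines (effective spacing = actual spacing x lines-per-shot
    / matrix_py).  ``physical_piecewise`` keeps the actual per-line spacing
    inside the keyhole and the ETS-shared spacing (actual / n_interleaves)
    in the periphery; both models span the same total readout duration.
    """

    UNIFORM_EFFECTIVE = "uniform_effective"
    PHYSICAL_PIECEWISE = "physical_piecewise"


class Region(str, Enum):
    KEYHOLE = "keyhole"
    PERIPHERY = "periphery"


@dataclass(frozen=True)
class SequenceParams:
    """Full parameterization of one readout scheme.

    Parameters
    ----------
    scheme : Scheme
        EPI (single shot, keyhole_fraction 1) or EPIK.
    matrix_py : int
        Number of phase-encode lines of the reconstructed image.
    matrix_ro : int
        Readout samples per line (defaults to ``matrix_py``).
    fov_mm : float
        Field of view along the phase-encode axis, millimetres.
    te_ms, tr_ms : float
        Echo time and repetition time, milliseconds.
    echo_spacing_ms : float
        Actual time between consecutively *acquired* lines within a shot.
    keyhole_fraction : float
        Fraction of k-space lines fully sampled on every shot.
    n_interleaves : int
        Number of shots over which the periphery is cycled.
    t2star_ms : float
        Effective transverse relaxation time used for decay weighting;
        ``math.inf`` disables decay.
    """

    scheme: Scheme = Scheme.EPI
    matrix_py: int = 64
    matrix_ro: int = 0
    fov_mm: float = 200.0
    te_ms: float = 30.0
    tr_ms: float = 2200.0
    echo_spacing_ms: float = 0.510
    keyhole_fraction: float = 1.0
    n_interleaves: int = 1
    t2star_ms: float = 66.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        if self.matrix_ro == 0:
            object.__setattr__(self, "matrix_ro", self.matrix_py)
        if not (0.0 < self.keyhole_fraction <= 1.0):
            raise ValueError("keyhole_fraction must lie in (0, 1]")
        for name in ("fov_mm", "te_ms", "tr_ms", "echo_spacing_ms", "t2star_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_interleaves < 1:
            raise ValueError("n_interleaves must be >= 1")
        kh = self.matrix_py * self.keyhole_fraction
        if abs(kh - round(kh)) > 1e-9:
            raise ValueError("matrix_py * keyhole_fraction must be an integer")
        if (self.matrix_py - round(kh)) % self.n_interleaves != 0:
            raise ValueError(
                "peripheral line count must be divisible by n_interleaves"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def keyhole_lines(self) -> int:
        return int(round(self.matrix_py * self.keyhole_fraction))

    @property
    def periphery_lines(self) -> int:
        return self.matrix_py - self.keyhole_lines

    @property
    def lines_per_shot(self) -> int:
        return self.keyhole_lines + self.periphery_lines // self.n_interleaves

    @property
    def effective_echo_spacing_ms(self) -> float:
        """Shot duration spread over all reconstructed lines (ms/line)."""
        return self.echo_spacing_ms * self.lines_per_shot / self.matrix_py

    @property
    def shot_duration_ms(self) -> float:
        return self.echo_spacing_ms * self.lines_per_shot

    def with_(self, **kw) -> "SequenceParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ScheduleEntry:
    line_index: int
    acq_time_ms: float
    region: Region


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered per-shot acquisition: which line, when, and in which region."""

    shot_index: int
    entries: Tuple[ScheduleEntry, ...]
    params: SequenceParams = field(repr=False, default=None)

    def __post_init__(self) -> None:
        times = [e.acq_time_ms for e in self.entries]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("acquisition times must be strictly increasing")

    @property
    def line_indices(self) -> List[int]:
        return [e.line_index for e in self.entries]

    def times_by_line(self) -> Dict[int, float]:
        return {e.line_index: e.acq_time_ms for e in self.entries}


@dataclass(frozen=True)
class EffectiveTimeMap:
    """One acquisition time (ms after excitation) per reconstructed line."""

    model: TimingModel
    times_ms: Tuple[float, ...]
    params: SequenceParams = field(repr=False, default=None)


def keyhole_bounds(params: SequenceParams) -> Tuple[int, int]:
    """Half-open line-index range [lo, hi) of the keyhole, centred on DC.

    The keyhole is placed symmetrically about the DC line ``matrix_py // 2``
    so that DC always lies inside it.
    """
    kh = params.keyhole_lines
    lo = (params.matrix_py - kh) // 2
    return lo, lo + kh


def _region_of(line: int, params: SequenceParams) -> Region:
    lo, hi = keyhole_bounds(params)
    return Region.KEYHOLE if lo <= line < hi else Region.PERIPHERY


def make_epi_schedule(params: SequenceParams, shot_index: int = 0) -> SamplingSchedule:
    """Linear bottom-to-top single-shot EPI ordering.

    Line ``j`` is read at ``te_ms + (j - matrix_py/2) * echo_spacing_ms`` so
    that the DC line coincides with the echo time.  ``shot_index`` only tags
    the schedule (every EPI shot is identical).
    """
    if params.scheme is not Scheme.EPI:
        raise ValueError("make_epi_schedule requires scheme=EPI")
    n = params.matrix_py
    entries = tuple(
        ScheduleEntry(j, params.te_ms + (j - n // 2) * params.echo_spacing_ms,
                      Region.KEYHOLE)
        for j in range(n)
    )
    return SamplingSchedule(shot_index, entries, params)


def make_epik_schedule(params: SequenceParams, shot_index: int) -> SamplingSchedule:
    """One EPIK excitation: periphery interleave + full keyhole.

    The shot reads, in k_y order, its bottom-periphery interleave (every
    ``n_interleaves``-th line with offset ``shot_index % n_interleaves``),
    the whole keyhole, then its top-periphery interleave; lines within each
    segment are spaced by the actual echo spacing.  Echo-time shifting is
    realized as per-shot dead-time adjustments between the segments: the
    interleave of shot *s* is delayed by ``(s mod n) * echo_spacing / n``
    while the keyhole stays anchored with its DC line on ``te_ms`` in every
    shot.  As a result each line's acquisition time is shot-invariant and
    the peripheral time map of shared multi-shot data increases smoothly
    with k_y at the effective spacing ``echo_spacing / n_interleaves``.
    """
    if params.scheme is not Scheme.EPIK:
        raise ValueError("make_epik_schedule requires scheme=EPIK")
    if shot_index < 0:
        raise ValueError("shot_index must be non-negative")
    n = params.matrix_py
    lo, hi = keyhole_bounds(params)
    offset = shot_index % params.n_interleaves

    order: List[int] = [j for j in range(0, lo) if j % params.n_interleaves == offset]
    order += list(range(lo, hi))
    order += [j for j in range(hi, n) if j % params.n_interleaves == offset]

    # shot-invariant per-line times: the ETS-consistent piecewise map
    tm = effective_line_times(params, TimingModel.PHYSICAL_PIECEWISE)
    entries = tuple(
        ScheduleEntry(j, tm.times_ms[j], _region_of(j, params)) for j in order
    )
    return SamplingSchedule(shot_index, entries, params)


def make_schedule(params: SequenceParams, shot_index: int = 0) -> SamplingSchedule:
    """Dispatch on scheme; EPI ignores ``shot_index`` ordering effects."""
    if params.scheme is Scheme.EPI:
        return make_epi_schedule(params, shot_index)
    return make_epik_schedule(params, shot_index)


def effective_line_times(
    params: SequenceParams,
    model: TimingModel | str = TimingModel.PHYSICAL_PIECEWISE,
) -> EffectiveTimeMap:
    """Acquisition time of every reconstructed k-space line.

    For EPI both models coincide with the single-shot schedule.  For EPIK,
    ``uniform_effective`` uses the effective spacing (actual x lines-per-shot
    / matrix_py; 0.445 ms for the 96-line, 3-interleave configuration) while
    ``physical_piecewise`` assigns ETS-consistent per-region spacings: the
    shared periphery advances at ``echo_spacing / n_interleaves`` per line,
    the keyhole at the actual echo spacing.  Both spans equal the shot
    duration, and the DC line sits at ``te_ms``.
    """
    model = TimingModel(model)
    n = params.matrix_py
    if model is TimingModel.UNIFORM_EFFECTIVE or params.scheme is Scheme.EPI:
        eff = params.effective_echo_spacing_ms
        times = tuple(params.te_ms + (j - n // 2) * eff for j in range(n))
        return EffectiveTimeMap(model, times, params)

    lo, hi = keyhole_bounds(params)
    d_kh = params.echo_spacing_ms
    d_per = params.echo_spacing_ms / params.n_interleaves
    # anchored at TE on the DC line; periphery continues at the ETS-shared
    # spacing beyond the keyhole edges
    times = []
    for j in range(n):
        if j < lo:
            t = params.te_ms + (lo - n // 2) * d_kh - (lo - j) * d_per
        elif j < hi:
            t = params.te_ms + (j - n // 2) * d_kh
        else:
            # first top-periphery line follows the keyhole at the actual
            # spacing (same shot), then the ETS-shared spacing resumes
            t = params.te_ms + (hi - n // 2) * d_kh + (j - hi) * d_per
        times.append(t)
    return EffectiveTimeMap(model, tuple(times), params)


def sampling_window(params: SequenceParams) -> Tuple[float, float]:
    """(t_min, t_max) of the effective readout window, ms after excitation.

    ``te_ms +/- (matrix_py / 2) * effective_spacing``; the window is
    symmetric about TE and its width is the shot duration.
    """
    half = params.matrix_py / 2 * params.effective_echo_spacing_ms
    return params.te_ms - half, params.te_ms + half


def periphery_update_rate(params: SequenceParams) -> float:
    """Refresh rate of the sparse periphery, Hz: ``1 / (TR * n_interleaves)``."""
    return 1.0 / (params.tr_ms / 1000.0 * params.n_interleaves)


def sliding_window_sources(
    scan_index: int, params: SequenceParams
) -> Dict[int, int]:
    """Map each reconstructed line to the scan that supplies it.

    Keyhole lines always come from the current scan; each peripheral line
    comes from the most recent of the ``n_interleaves`` trailing scans whose
    interleave offset covers it.  Raises for scans before the first complete
    sliding window (``scan_index < n_interleaves - 1``).
    """
    if scan_index < params.n_interleaves - 1:
        raise ValueError(
            f"scan {scan_index} is not yet reconstructable: the sliding window "
            f"needs {params.n_interleaves} consecutive scans"
        )
    lo, hi = keyhole_bounds(params)
    sources: Dict[int, int] = {}
    for j in range(params.matrix_py):
        if lo <= j < hi:
            sources[j] = scan_index
        else:
            # most recent scan s in the window with s % n == j % n
            delta = (scan_index - j) % params.n_interleaves
            sources[j] = scan_index - delta
    return sources


def schedule_to_frame(schedules: List[SamplingSchedule]) -> pd.DataFrame:
    """Tabulate schedules as (shot_index, acq_order, line_index, region,
    acq_time_ms) rows, ready for CSV export."""
    rows = [
        {
            "shot_index": s.shot_index,
            "acq_order": m,
            "line_index": e.line_index,
            "region": e.region.value,
            "acq_time_ms": e.acq_time_ms,
        }
        for s in schedules
        for m, e in enumerate(s.entries)
    ]
    return pd.DataFrame(rows)
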