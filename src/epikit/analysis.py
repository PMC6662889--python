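"""Functional metrics for reconstructed series: tSNR, GLM, autocorrelation.

Desk-scale analogue of a first-level block-design analysis: pixelwise
ordinary least squares against a design of [constant, HRF-convolved boxcar,
its temporal derivative, linear drift], temporal SNR maps, percent signal
change, and lag-k autocorrelation of ROI-mean residuals (the quantity that
would reveal temporal structure introduced by the sliding-window sharing of
peripheral k-space).  No smoothing, realignment or normalization: the
synthetic data contain no motion or anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .phantom import Paradigm, boxcar, canonical_hrf, _convolved_response
from .recon import VolumeSeries

__all__ = [
    "GlmResult",
    "SeriesMetrics",
    "design_matrix",
    "tsnr",
    "glm_activation",
    "residual_autocorrelation",
    "series_metrics",
    "compare_schemes",
]


@dataclass
class GlmResult:
    """Per-pixel OLS fit of a block-design model."""

    beta: np.ndarray  # (n_regressors, ny, nx)
    t_map: np.ndarray  # task-regressor t statistic, (ny, nx)
    residuals: np.ndarray  # (n_frames, ny, nx)
    design: np.ndarray  # (n_frames, n_regressors)
    design_names: tuple
    roi_stats: pd.DataFrame  # per-ROI amplitude/t from the ROI-mean fit


@dataclass
class SeriesMetrics:
    """Summary metrics of one reconstructed series."""

    scheme: str
    tsnr_map: np.ndarray = field(repr=False)
    tsnr_summary: float = np.nan
    roi_percent_change: Dict[str, float] = field(default_factory=dict)
    roi_t: Dict[str, float] = field(default_factory=dict)
    roi_autocorr: Dict[str, np.ndarray] = field(default_factory=dict)


def design_matrix(paradigm: Paradigm, frame_times_s: np.ndarray) -> tuple[np.ndarray, tuple]:
    """[constant, task (unit plateau), temporal derivative, linear drift]
    sampled at the frame times."""
    t = np.asarray(frame_times_s, float)
    grid_t, resp = _convolved_response(paradigm)
    task = np.interp(t, grid_t, resp)
    deriv = np.interp(t, grid_t, np.gradient(resp, grid_t))
    drift = np.linspace(-0.5, 0.5, t.size)
    X = np.column_stack([np.ones_like(t), task, deriv, drift])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, ("constant", "task", "task_derivative", "drift")


def tsnr(series: VolumeSeries, mask: np.ndarray | None = None):
    """Temporal SNR map (mean / SD over frames) and its in-mask mean.

    Zero-variance pixels are reported as ``inf`` in the map and excluded
    from the summary.
    """
    if series.n_frames < 3:
        raise ValueError("tSNR needs at least 3 frames")
    mean = series.frames.mean(axis=0)
    sd = series.frames.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    if mask is None:
        mask = np.ones(mean.shape, bool)
    vals = tmap[mask & np.isfinite(tmap)]
    summary = float(vals.mean()) if vals.size else float("nan")
    return tmap, summary


def glm_activation(
    series: VolumeSeries,
    paradigm: Paradigm,
    roi_masks: Dict[str, np.ndarray] | None = None,
) -> GlmResult:
    """Pixelwise OLS of the block-design model; ROI-level stats from the
    same fit applied to ROI-mean time series.

    The task regressor has unit plateau, so ``100 * beta_task / beta_const``
    is the recovered percent signal change.
    """
    X, names = design_matrix(paradigm, series.frame_times_s())
    n, ny, nx = series.frames.shape
    Y = series.frames.reshape(n, -1)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), np.nan)

    rows = []
    for name, mask in (roi_masks or {}).items():
        y = series.frames[:, mask].mean(axis=1)
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ b
        s2 = float(r @ r) / dof
        t_roi = b[1] / np.sqrt(s2 * xtx_inv[1, 1]) if s2 > 0 else np.nan
        pct = 100.0 * b[1] / b[0] if b[0] != 0 else np.nan
        rows.append(
            {"roi": name, "beta": b[1], "t": t_roi, "percent_change": pct, "dof": dof}
        )
    return GlmResult(
        beta=beta.reshape(X.shape[1], ny, nx),
        t_map=t_map.reshape(ny, nx),
        residuals=resid.reshape(n, ny, nx),
        design=X,
        design_names=names,
        roi_stats=pd.DataFrame(rows),
    )


def residual_autocorrelation(
    glm: GlmResult, roi: np.ndarray, max_lag: int = 5
) -> np.ndarray:
    """Sample autocorrelation (lags 1..max_lag) of ROI-mean GLM residuals."""
    r = glm.residuals[:, roi].mean(axis=1)
    if r.size <= max_lag + 2:
        raise ValueError("residual series too short for the requested lags")
    if np.allclose(r, r[0]):
        raise ValueError("degenerate (constant) residual series")
    r = r - r.mean()
    denom = float(r @ r)
    return np.array([float(r[k:] @ r[:-k]) / denom for k in range(1, max_lag + 1)])


def series_metrics(
    series: VolumeSeries,
    paradigm: Paradigm,
    roi_masks: Dict[str, np.ndarray],
    object_mask: np.ndarray | None = None,
    scheme: str = "",
    max_lag: int = 5,
) -> SeriesMetrics:
    """tSNR + GLM + autocorrelation bundle for one series."""
    tmap, summary = tsnr(series, object_mask)
    glm = glm_activation(series, paradigm, roi_masks)
    stats = glm.roi_stats.set_index("roi")
    ac = {}
    for name, mask in roi_masks.items():
        try:
            ac[name] = residual_autocorrelation(glm, mask, max_lag)
        except ValueError:
            ac[name] = np.full(max_lag, np.nan)
    return SeriesMetrics(
        scheme=scheme,
        tsnr_map=tmap,
        tsnr_summary=summary,
        roi_percent_change=stats["percent_change"].to_dict(),
        roi_t=stats["t"].to_dict(),
        roi_autocorr=ac,
    )


def compare_schemes(a: SeriesMetrics, b: SeriesMetrics) -> pd.DataFrame:
    """Side-by-side table of two series' metrics (no recomputation)."""
    if set(a.roi_percent_change) != set(b.roi_percent_change):
        raise ValueError("metrics were computed on mismatched phantom configs")
    ca, cb = a.scheme or "a", b.scheme or "b"
    if ca == cb:
        ca, cb = f"{ca}_a", f"{cb}_b"
    rows = [
        {"metric": "tsnr_summary", "roi": "", ca: a.tsnr_summary, cb: b.tsnr_summary}
    ]
    for roi in sorted(a.roi_percent_change):
        rows.append(
            {"metric": "percent_change", "roi": roi,
             ca: a.roi_percent_change[roi], cb: b.roi_percent_change[roi]}
        )
        rows.append(
            {"metric": "t_stat", "roi": roi, ca: a.roi_t[roi], cb: b.roi_t[roi]}
        )
        for k in range(len(a.roi_autocorr[roi])):
            rows.append(
                {"metric": f"autocorr_lag{k + 1}", "roi": roi,
                 ca: a.roi_autocorr[roi][k], cb: b.roi_autocorr[roi][k]}
            )
    df = pd.DataFrame(rows)
    df["delta"] = df[cb] - df[ca]
    return df
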