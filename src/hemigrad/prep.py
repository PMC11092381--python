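"""Denoising of parcellated resting-state time series.

Implements the scrubbing-and-filtering recipe applied before
connectivity estimation: motion-based volume censoring (FD/DVARS with
neighbour flagging), cubic-spline interpolation of censored volumes,
linear detrending, first-order zero-phase Butterworth band-pass
(0.01-0.1 Hz by default), dropping of censored volumes, nuisance
regression performed *orthogonally to temporal filtering* (confounds are
passed through the identical filter before regression), optional global
signal regression, and per-region z-scoring.

The module is format-agnostic about confounds: motion-parameter
expansions (e.g. the 24-parameter set) are expected as a ready-made
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.interpolate
import scipy.signal


@dataclass(frozen=True)
class MotionTrace:
    """Per-volume head-motion summaries: FD (mm) and DVARS."""

    fd: np.ndarray
    dvars: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        fd = np.asarray(self.fd, dtype=float)
        dv = np.asarray(self.dvars, dtype=float)
        if fd.shape != dv.shape or fd.ndim != 1:
            raise ValueError("fd and dvars must be 1-D and the same length")
        if (fd < 0).any() or (dv < 0).any():
            raise ValueError("fd and dvars must be nonnegative")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "fd", fd)
        object.__setattr__(self, "dvars", dv)

    def __len__(self) -> int:
        return len(self.fd)


@dataclass(frozen=True)
class CensorMask:
    """Boolean keep-mask over volumes plus the censored count."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "keep", np.asarray(self.keep, dtype=bool))

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def censor_mask(
    motion: MotionTrace,
    fd_thresh: float = 0.35,
    dvars_thresh: float = 50.0,
    n_forward: int = 1,
    n_back: int = 2,
) -> CensorMask:
    """Flag high-motion volumes and their neighbours.

    A volume is censored iff it is within ``n_back`` volumes before or
    ``n_forward`` volumes after (or is) a volume with
    ``fd > fd_thresh`` or ``dvars > dvars_thresh``. Defaults follow the
    '1 forward and 2 back' neighbour rule; indices are clipped at the
    series bounds.
    """
    if fd_thresh <= 0 or dvars_thresh <= 0:
        raise ValueError("thresholds must be positive")
    n = len(motion)
    bad = (motion.fd > fd_thresh) | (motion.dvars > dvars_thresh)
    censored = np.zeros(n, dtype=bool)
    for w in np.flatnonzero(bad):
        lo = max(0, w - n_back)
        hi = min(n, w + n_forward + 1)
        censored[lo:hi] = True
    return CensorMask(keep=~censored)


def min_duration_ok(mask: CensorMask, tr: float, min_seconds: float = 240.0) -> bool:
    """True iff the kept volumes amount to at least ``min_seconds`` of data."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    return mask.n_kept * tr >= min_seconds


def _bandpass(x: np.ndarray, band: tuple[float, float], tr: float) -> np.ndarray:
    """First-order zero-phase (forward-backward) Butterworth band-pass."""
    fs = 1.0 / tr
    nyq = fs / 2.0
    lo, hi = band
    if not 0.0 < lo < hi < nyq:
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyq:.4g})")
    b, a = scipy.signal.butter(1, [lo, hi], btype="bandpass", fs=fs)
    return scipy.signal.filtfilt(b, a, x, axis=0)


def denoise(
    ts: np.ndarray,
    motion: MotionTrace | None = None,
    confounds: np.ndarray | None = None,
    band: tuple[float, float] = (0.01, 0.1),
    gsr: bool = False,
    fd_thresh: float = 0.35,
    dvars_thresh: float = 50.0,
    tr: float | None = None,
) -> tuple[np.ndarray, CensorMask]:
    """Clean a timepoints x regions matrix; returns (cleaned, mask).

    Pipeline order: censor-mask from motion -> cubic-spline interpolation
    of censored volumes -> linear detrend -> band-pass -> drop censored
    volumes -> confound regression (confounds detrended and band-passed
    with the same filter, so regression is orthogonal to filtering;
    region-mean global signal appended when ``gsr``) -> per-region
    z-score. Output has one row per kept volume.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be 2-D (timepoints x regions)")
    n_vol = ts.shape[0]
    if motion is not None:
        if len(motion) != n_vol:
            raise ValueError("motion trace length does not match time series")
        tr = motion.tr if tr is None else tr
        mask = censor_mask(motion, fd_thresh=fd_thresh, dvars_thresh=dvars_thresh)
    else:
        mask = CensorMask(keep=np.ones(n_vol, dtype=bool))
    if tr is None:
        raise ValueError("tr must be given (directly or via the motion trace)")
    if mask.n_kept < 2:
        raise ValueError("fewer than 2 volumes survive censoring")
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] == 1 and n_vol != 1:
            confounds = confounds.T
        if confounds.shape[0] != n_vol:
            raise ValueError("confound row count must equal volume count")

    keep = mask.keep
    # 1. interpolate censored volumes (cubic spline through kept volumes)
    x = ts.copy()
    if mask.n_censored:
        t_all = np.arange(n_vol, dtype=float)
        spl = scipy.interpolate.CubicSpline(t_all[keep], ts[keep], axis=0)
        x[~keep] = spl(t_all[~keep])
    # 2. detrend, 3. band-pass
    x = scipy.signal.detrend(x, axis=0, type="linear")
    x = _bandpass(x, band, tr)
    # 4. drop censored volumes
    x = x[keep]
    # 5. nuisance regression, orthogonal to filtering
    design_parts = [np.ones((mask.n_kept, 1))]
    if confounds is not None:
        c = scipy.signal.detrend(confounds, axis=0, type="linear")
        c = _bandpass(c, band, tr)
        design_parts.append(c[keep])
    if gsr:
        design_parts.append(x.mean(axis=1, keepdims=True))
    X = np.hstack(design_parts)
    if X.shape[1] > 1:
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        x = x - X @ beta
    else:
        x = x - x.mean(axis=0, keepdims=True)
    # 6. standardization
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd < 1e-12)
    if dead.size:
        raise ValueError(
            f"zero-variance region(s) after cleaning at column(s) {dead.tolist()}"
        )
    x = (x - x.mean(axis=0, keepdims=True)) / sd
    return x, mask
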