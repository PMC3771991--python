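"""Temporal cleaning of per-variable signals.

The steps mirror the standard resting-state pipeline once spatial
preprocessing is done upstream: motion scrubbing based on frame-wise
displacement (FD), nuisance regression (head motion, CSF, white matter,
global signal), linear detrending and band-pass filtering (0.01-0.08 Hz by
default).  Frame-wise displacement uses the Power formulation: the sum of
absolute backward differences of the six rigid-body parameters, with
rotations converted to arc length on a configurable-radius sphere (50 mm
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import TimeSeriesSet


@dataclass
class NuisanceSet:
    """T x R matrix of confound regressors with names."""

    regressors: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] < 1:
            raise ValueError("need at least one regressor")
        if self.names is None:
            self.names = [f"r{i + 1}" for i in range(self.regressors.shape[1])]
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("names do not match regressor count")
        zero = np.all(self.regressors == 0, axis=0)
        if zero.any():
            raise ValueError(
                f"constant-zero regressor column(s): {list(np.flatnonzero(zero))}"
            )


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Per-frame head-motion summary from six rigid-body parameters.

    ``motion`` is T x 6: three translations in mm then three rotations in
    radians.  FD[0] = 0 and FD[t] is the sum of absolute backward
    differences, rotations mapped to displacement on a sphere of
    ``head_radius_mm``.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] < 6:
        raise ValueError(f"motion table must be T x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if head_radius_mm <= 0:
        raise ValueError("head radius must be positive")
    d = np.abs(np.diff(motion[:, :6], axis=0))
    d[:, 3:6] *= head_radius_mm
    fd = np.zeros(motion.shape[0])
    fd[1:] = d.sum(axis=1)
    return fd


def scrub_interpolate(
    ts: TimeSeriesSet, fd: np.ndarray, threshold_mm: float = 0.5
) -> tuple[TimeSeriesSet, list[int]]:
    """Replace frames with FD above threshold by linear interpolation.

    Censored frames between two clean frames get the linear interpolation of
    their nearest uncensored neighbours; censored frames at the boundaries
    get a copy of the nearest uncensored value.  T is unchanged.  Returns
    the cleaned series and the censored index list.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (ts.n_times,):
        raise ValueError(f"fd length {fd.size} != T {ts.n_times}")
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    bad = fd > threshold_mm
    censored = list(np.flatnonzero(bad))
    if not censored:
        return ts.replace(ts.data.copy()), []
    good = np.flatnonzero(~bad)
    if good.size == 0:
        raise ValueError("all frames exceed the FD threshold")
    t = np.arange(ts.n_times)
    out = ts.data.copy()
    for j in range(ts.n_vars):
        # np.interp clamps to the boundary values, which implements the
        # nearest-uncensored rule at run edges
        out[bad, j] = np.interp(t[bad], good, ts.data[good, j])
    return ts.replace(out, censored_frames=censored), censored


def regress_nuisance(ts: TimeSeriesSet, nuisance: NuisanceSet) -> TimeSeriesSet:
    """Replace every column by its OLS residual on [intercept + regressors]."""
    r = nuisance.regressors
    if r.shape[0] != ts.n_times:
        raise ValueError(
            f"nuisance rows {r.shape[0]} != time points {ts.n_times}"
        )
    design = np.column_stack([np.ones(ts.n_times), r])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which regressors are collinear via the QR diagonal
        _, rr = np.linalg.qr(design)
        diag = np.abs(np.diag(rr))
        bad = [
            nuisance.names[i - 1]
            for i in range(1, design.shape[1])
            if diag[i] < 1e-10 * diag.max()
        ]
        raise ValueError(f"rank-deficient nuisance design; collinear: {bad}")
    coef, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ coef
    return ts.replace(resid, nuisance_removed=list(nuisance.names))


def detrend_bandpass(
    ts: TimeSeriesSet,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 2,
) -> TimeSeriesSet:
    """Remove the linear trend, then zero-phase band-pass filter each column.

    The filter is a Butterworth design of ``order`` applied forward and
    backward (``sosfiltfilt``), so the effective attenuation is doubled in
    dB and the phase is exactly zero — important here because phase shifts
    would corrupt the temporal-precedence structure that Granger causality
    measures.  ``low_hz`` = 0 degrades to a pure low-pass.
    """
    nyq = 1.0 / (2.0 * ts.dt)
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) outside (0, Nyquist={nyq:g})"
        )
    data = sps.detrend(ts.data, axis=0, type="linear")
    if low_hz > 0:
        sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.dt, output="sos")
    else:
        sos = sps.butter(order, high_hz, btype="lowpass", fs=1.0 / ts.dt, output="sos")
    out = sps.sosfiltfilt(sos, data, axis=0)
    return ts.replace(np.ascontiguousarray(out), band=(low_hz, high_hz))


def preprocess_pipeline(
    ts: TimeSeriesSet,
    motion: np.ndarray | None = None,
    nuisance: NuisanceSet | None = None,
    fd_threshold_mm: float = 0.5,
    head_radius_mm: float = 50.0,
    band: tuple[float, float] = (0.01, 0.08),
    filter_order: int = 2,
) -> tuple[TimeSeriesSet, list[int]]:
    """Scrub -> nuisance regression -> detrend + band-pass, in that order."""
    censored: list[int] = []
    if motion is not None:
        fd = framewise_displacement(motion, head_radius_mm)
        ts, censored = scrub_interpolate(ts, fd, fd_threshold_mm)
    if nuisance is not None:
        ts = regress_nuisance(ts, nuisance)
    ts = detrend_bandpass(ts, band[0], band[1], order=filter_order)
    return ts, censored
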