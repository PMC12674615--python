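"""Fiber-photometry pipeline: trim, despike, isosbestic ΔF/F, PETHs.

The recording carries two channels sampled on the same clock: the
calcium-dependent signal (470 nm excitation) and the calcium-independent
isosbestic control (405 nm), which tracks photobleaching and motion.
The pipeline mirrors standard practice for this preparation:

1. drop the first minute, where the fast component of photobleaching
   dominates;
2. remove point artifacts with a Hampel filter (running median ±
   ``n_mad`` scaled MADs);
3. least-squares fit of the control channel to the signal channel,
   F405_fitted = a*F405 + b;
4. ΔF/F = (F470 − F405_fitted) / F405_fitted;
5. optional z-scoring against a baseline window or the whole trace;
6. peri-event time histograms (PETHs) around stimulus onsets, per-trial
   peak statistics in the first post-onset second, and counts of trials
   whose z-scored peak exceeds a threshold (default 2).

TTL pulses recorded on both the photometry and the video clock anchor
the affine map between the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    DegenerateFitError,
    EmptyPETHError,
    InvalidBaselineError,
    InvalidParameterError,
    OutOfRangeError,
    PairingError,
    TooShortError,
)

logger = logging.getLogger(__name__)

# Consistency constant making the MAD an unbiased sd estimate for
# Gaussian noise; the Hampel threshold is n_mad * 1.4826 * MAD.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class PhotometryRecording:
    """Dual-channel fluorescence trace with TTL event timestamps."""

    t: np.ndarray
    f_signal: np.ndarray
    f_control: np.ndarray
    ttl_times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f_signal", np.asarray(self.f_signal, dtype=float))
        object.__setattr__(self, "f_control", np.asarray(self.f_control, dtype=float))
        object.__setattr__(self, "ttl_times_s", np.asarray(self.ttl_times_s, dtype=float))
        if len(self.f_signal) != len(t) or len(self.f_control) != len(t):
            raise InvalidParameterError("channel lengths differ from time base")
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise InvalidParameterError("time base must be strictly increasing")
            if (dt.max() - dt.min()) > 1e-4 * dt.mean():
                raise InvalidParameterError(
                    "time base must be uniform to within 1 part in 1e4"
                )

    @property
    def fs(self) -> float:
        """Sampling rate (samples/s)."""
        if len(self.t) < 2:
            raise TooShortError("need >= 2 samples to infer a sampling rate")
        return 1.0 / float(np.mean(np.diff(self.t)))

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


@dataclass(frozen=True)
class DffTrace:
    """ΔF/F trace, optionally z-scored against a stated baseline."""

    t: np.ndarray
    dff: np.ndarray
    is_zscored: bool = False
    baseline_window_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "dff", np.asarray(self.dff, dtype=float))
        if len(self.t) != len(self.dff):
            raise InvalidParameterError("t and dff lengths differ")
        if not np.all(np.isfinite(self.dff)):
            raise InvalidParameterError("dff must be finite everywhere")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.t)))


@dataclass(frozen=True)
class PETH:
    """Event-aligned trial matrix with per-sample mean and sem.

    ``time_s`` is relative to onset (column 0 is the window start);
    one row per usable event.
    """

    time_s: np.ndarray
    trial_matrix: np.ndarray
    event_onsets_s: np.ndarray
    window_s: tuple[float, float]

    @property
    def n_trials(self) -> int:
        return self.trial_matrix.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.trial_matrix.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        if self.n_trials < 2:
            return np.zeros(self.trial_matrix.shape[1])
        return self.trial_matrix.std(axis=0, ddof=1) / np.sqrt(self.n_trials)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.trial_matrix.T,
            columns=[f"trial{i + 1}" for i in range(self.n_trials)],
        )
        df.insert(0, "time_s", self.time_s)
        df["mean"] = self.mean
        df["sem"] = self.sem
        return df


@dataclass(frozen=True)
class TrialResponseSummary:
    """Per-trial peak statistics and the suprathreshold trial count."""

    peak_post: np.ndarray
    peak_baseline: np.ndarray
    threshold: float
    post_window_s: tuple[float, float]
    baseline_window_s: tuple[float, float]

    @property
    def n_trials(self) -> int:
        return len(self.peak_post)

    @property
    def n_suprathreshold(self) -> int:
        return int(np.sum(self.peak_post > self.threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "peak_post": self.peak_post,
                "peak_baseline": self.peak_baseline,
                "suprathreshold": self.peak_post > self.threshold,
            }
        )


@dataclass(frozen=True)
class ClockMap:
    """Affine map from video time to photometry time: t_phot = drift*t_video + offset."""

    offset_s: float
    drift: float = 1.0

    def video_to_photometry(self, t_video_s):
        return self.drift * np.asarray(t_video_s, dtype=float) + self.offset_s

    def photometry_to_video(self, t_phot_s):
        return (np.asarray(t_phot_s, dtype=float) - self.offset_s) / self.drift


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def trim_initial(rec: PhotometryRecording, trim_s: float = 60.0) -> PhotometryRecording:
    """Drop all samples earlier than ``trim_s`` after the recording start.

    Removes the segment dominated by initial photobleaching.  TTLs
    falling in the removed segment are dropped with a logged warning.
    """
    if trim_s < 0:
        raise InvalidParameterError(f"trim_s must be >= 0, got {trim_s}")
    if trim_s == 0:
        return rec
    t0 = rec.t[0] + trim_s
    keep = rec.t >= t0
    if not keep.any():
        raise TooShortError(
            f"recording of {rec.duration_s:.1f} s is shorter than trim_s={trim_s} s"
        )
    dropped = int(np.sum(rec.ttl_times_s < t0))
    if dropped:
        logger.warning("trim_initial: dropping %d TTL(s) before t=%.1f s", dropped, t0)
    return PhotometryRecording(
        rec.t[keep],
        rec.f_signal[keep],
        rec.f_control[keep],
        rec.ttl_times_s[rec.ttl_times_s >= t0],
    )


def _hampel(x: np.ndarray, window: int, n_mad: float) -> tuple[np.ndarray, np.ndarray]:
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    windows = sliding_window_view(padded, window)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    bad = np.abs(x - med) > n_mad * MAD_SCALE * mad
    out = x.copy()
    out[bad] = med[bad]
    return out, bad


def remove_point_artifacts(
    rec: PhotometryRecording, window: int = 11, n_mad: float = 5.0
) -> PhotometryRecording:
    """Hampel-filter both channels: replace running-median outliers.

    A sample deviating from its window's median by more than
    ``n_mad`` x 1.4826 x the window MAD is replaced by that median.  On
    locally monotone (artifact-free) traces the window median equals
    the centre sample, so the filter is an exact no-op there.  On heavy
    white noise the running MAD is itself noisy, so a small fraction of
    clean samples (about 0.4% at the defaults) is replaced by a nearby
    median — a perturbation bounded by the local noise scale.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError(f"window must be odd and >= 3, got {window}")
    sig, bad_s = _hampel(rec.f_signal, window, n_mad)
    ctl, bad_c = _hampel(rec.f_control, window, n_mad)
    n_bad = int(bad_s.sum() + bad_c.sum())
    if n_bad:
        logger.info("remove_point_artifacts: corrected %d sample(s)", n_bad)
    return PhotometryRecording(rec.t, sig, ctl, rec.ttl_times_s)


def fit_control_to_signal(rec: PhotometryRecording) -> tuple[np.ndarray, float, float]:
    """Least-squares fit of the isosbestic channel onto the signal channel.

    Returns ``(fitted, a, b)`` with fitted = a*f_control + b minimizing
    the squared error against f_signal, sample by sample.
    """
    if len(rec.t) < 2:
        raise TooShortError("need >= 2 samples for the isosbestic fit")
    ctl = rec.f_control
    if np.ptp(ctl) == 0:
        raise DegenerateFitError("control channel is constant; fit is degenerate")
    a, b = np.polyfit(ctl, rec.f_signal, 1)
    return a * ctl + b, float(a), float(b)


def compute_dff(rec: PhotometryRecording, fitted: np.ndarray | None = None) -> DffTrace:
    """ΔF/F = (f_signal − fitted control) / fitted control.

    Removes bleaching and motion components shared with the isosbestic
    channel.  The fitted control is computed by
    :func:`fit_control_to_signal` unless supplied; it must be strictly
    positive.
    """
    if fitted is None:
        fitted, _, _ = fit_control_to_signal(rec)
    else:
        fitted = np.asarray(fitted, dtype=float)
    bad = np.flatnonzero(fitted <= 0)
    if bad.size:
        raise InvalidBaselineError(
            f"fitted control non-positive at {bad.size} sample(s), "
            f"first indices {bad[:5].tolist()}"
        )
    return DffTrace(rec.t, (rec.f_signal - fitted) / fitted)


def zscore_trace(
    dff: DffTrace, baseline: "tuple[float, float] | str" = "whole-trace"
) -> DffTrace:
    """Z-score a ΔF/F trace against a baseline interval or the whole trace."""
    if baseline == "whole-trace":
        mask = np.ones(len(dff.t), dtype=bool)
        window = (float(dff.t[0]), float(dff.t[-1]))
    else:
        t0, t1 = baseline
        mask = (dff.t >= t0) & (dff.t < t1)
        window = (float(t0), float(t1))
    if mask.sum() < 2:
        raise DegenerateFitError("baseline segment needs >= 2 samples")
    mu = float(np.mean(dff.dff[mask]))
    sd = float(np.std(dff.dff[mask], ddof=1))
    if sd == 0:
        raise DegenerateFitError("baseline segment has zero variance")
    return DffTrace(dff.t, (dff.dff - mu) / sd, is_zscored=True, baseline_window_s=window)


def smooth_trace(dff: DffTrace, window_s: float) -> DffTrace:
    """Boxcar-smooth a trace (moving average over ``window_s`` seconds).

    Used to stabilize peak statistics read off PETHs; off by default in
    the pipeline.
    """
    if window_s <= 0:
        raise InvalidParameterError("window_s must be > 0")
    n = max(1, int(round(window_s * dff.fs)))
    if n == 1:
        return dff
    kernel = np.ones(n) / n
    sm = np.convolve(dff.dff, kernel, mode="same")
    # convolve 'same' divides by fewer true samples near the edges; renormalize
    norm = np.convolve(np.ones_like(dff.dff), kernel, mode="same")
    return replace(dff, dff=sm / norm)


def process_recording(
    rec: PhotometryRecording,
    trim_s: float = 60.0,
    despike_window: int = 11,
    despike_n_mad: float = 5.0,
    zscore: "str | tuple[float, float] | None" = "whole-trace",
) -> DffTrace:
    """Standard pipeline: trim -> despike -> isosbestic fit -> ΔF/F (-> z)."""
    rec = trim_initial(rec, trim_s)
    rec = remove_point_artifacts(rec, despike_window, despike_n_mad)
    dff = compute_dff(rec)
    if zscore is not None:
        dff = zscore_trace(dff, zscore)
    return dff


def synchronize(
    ttl_photometry_s: np.ndarray, ttl_video_frames: np.ndarray, fps: float
) -> ClockMap:
    """Affine video->photometry clock map from paired TTL trains.

    TTLs are paired in order; with a single pair the map is a pure
    offset, with more it is the least-squares affine fit.
    """
    tp = np.asarray(ttl_photometry_s, dtype=float)
    tv = np.asarray(ttl_video_frames, dtype=float) / fps
    if len(tp) == 0 or len(tv) == 0:
        raise PairingError("need at least one TTL on each clock")
    if len(tp) != len(tv):
        raise PairingError(
            f"TTL counts differ: {len(tp)} photometry vs {len(tv)} video"
        )
    if len(tp) == 1:
        return ClockMap(offset_s=float(tp[0] - tv[0]), drift=1.0)
    drift, offset = np.polyfit(tv, tp, 1)
    return ClockMap(offset_s=float(offset), drift=float(drift))


def build_peth(
    trace: DffTrace,
    onsets_s: np.ndarray,
    window_s: tuple[float, float] = (-5.0, 10.0),
    trialwise_zscore: bool = False,
    baseline_window_s: tuple[float, float] = (-5.0, 0.0),
    smooth_s: float | None = None,
) -> PETH:
    """Extract event-aligned trials on a common time grid.

    Trials are resampled by linear interpolation onto a grid at the
    trace's own sampling interval.  Onsets without full window coverage
    are dropped with a logged warning; none usable raises
    :class:`EmptyPETHError`.  With ``trialwise_zscore`` each row is
    z-scored against its own pre-onset ``baseline_window_s``.  An
    optional boxcar of ``smooth_s`` seconds is applied to each row after
    any z-scoring.
    """
    pre, post = window_s
    if not pre < post:
        raise InvalidParameterError(f"window must satisfy pre < post, got {window_s}")
    onsets = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    usable = [
        o for o in onsets if o + pre >= trace.t[0] and o + post <= trace.t[-1]
    ]
    dropped = len(onsets) - len(usable)
    if dropped:
        logger.warning("build_peth: dropped %d onset(s) without full window coverage", dropped)
    if not usable:
        raise EmptyPETHError("no usable onsets with full window coverage")
    dt = 1.0 / trace.fs
    grid = np.arange(pre, post, dt)
    rows = np.stack([np.interp(o + grid, trace.t, trace.dff) for o in usable])
    if trialwise_zscore:
        b0, b1 = baseline_window_s
        bmask = (grid >= b0) & (grid < b1)
        if bmask.sum() < 2:
            raise InvalidParameterError("trial baseline window too short for z-scoring")
        mu = rows[:, bmask].mean(axis=1, keepdims=True)
        sd = rows[:, bmask].std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateFitError("a trial baseline has zero variance")
        rows = (rows - mu) / sd
    if smooth_s:
        n = max(1, int(round(smooth_s / dt)))
        if n > 1:
            kernel = np.ones(n) / n
            norm = np.convolve(np.ones(rows.shape[1]), kernel, mode="same")
            rows = np.stack(
                [np.convolve(r, kernel, mode="same") / norm for r in rows]
            )
    return PETH(grid, rows, np.asarray(usable), window_s)


def _window_slice(peth: PETH, window: tuple[float, float]) -> np.ndarray:
    w0, w1 = window
    if w0 < peth.window_s[0] or w1 > peth.window_s[1]:
        raise OutOfRangeError(
            f"window {window} outside PETH window {peth.window_s}"
        )
    mask = (peth.time_s >= w0) & (peth.time_s < w1)
    if not mask.any():
        raise OutOfRangeError(f"window {window} contains no PETH samples")
    return mask


def peak_response(
    peth: PETH,
    post_window_s: tuple[float, float] = (0.0, 1.0),
    baseline_window_s: tuple[float, float] = (-1.0, 0.0),
    threshold: float = 2.0,
) -> TrialResponseSummary:
    """Per-trial maxima in the first post-onset window vs the mirrored baseline.

    The response statistic is the maximum over ``post_window_s`` (the
    first post-onset second by default); the baseline statistic is the
    same maximum over the mirrored pre-onset window so the two are
    comparable.  The paired post-vs-baseline comparison across trials is
    run by the stats module.
    """
    post = peth.trial_matrix[:, _window_slice(peth, post_window_s)].max(axis=1)
    base = peth.trial_matrix[:, _window_slice(peth, baseline_window_s)].max(axis=1)
    return TrialResponseSummary(post, base, threshold, post_window_s, baseline_window_s)


def count_suprathreshold_trials(
    peth: PETH,
    threshold: float = 2.0,
    post_window_s: tuple[float, float] = (0.0, 1.0),
) -> int:
    """Number of trials whose post-window peak strictly exceeds ``threshold``.

    With a z-scored PETH and the default threshold this is the
    "trials with ΔF/F > 2 (z units)" count.
    """
    post = peth.trial_matrix[:, _window_slice(peth, post_window_s)].max(axis=1)
    return int(np.sum(post > threshold))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_photometry_csv(path, ttl_path=None) -> PhotometryRecording:
    """Read a recording from CSV with columns time_s, f470, f405.

    TTL timestamps, if any, come from a one-column CSV (``ttl_path``).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "f470", "f405"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    ttl = np.array([])
    if ttl_path is not None:
        ttl_df = pd.read_csv(ttl_path)
        ttl = ttl_df.iloc[:, 0].to_numpy(float)
    return PhotometryRecording(
        df["time_s"].to_numpy(float),
        df["f470"].to_numpy(float),
        df["f405"].to_numpy(float),
        ttl,
    )


def write_photometry_csv(rec: PhotometryRecording, path, ttl_path=None) -> None:
    pd.DataFrame(
        {"time_s": rec.t, "f470": rec.f_signal, "f405": rec.f_control}
    ).to_csv(path, index=False)
    if ttl_path is not None:
        pd.DataFrame({"ttl_time_s": rec.ttl_times_s}).to_csv(ttl_path, index=False)


def read_photometry_hdf5(path, group: str = "/") -> PhotometryRecording:
    """Read a recording from an HDF5 group with datasets t, f470, f405, ttl."""
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh[group]
        ttl = g["ttl"][()] if "ttl" in g else np.array([])
        return PhotometryRecording(g["t"][()], g["f470"][()], g["f405"][()], ttl)


def write_photometry_hdf5(rec: PhotometryRecording, path, group: str = "/") -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.require_group(group)
        g.create_dataset("t", data=rec.t)
        g.create_dataset("f470", data=rec.f_signal)
        g.create_dataset("f405", data=rec.f_control)
        g.create_dataset("ttl", data=rec.ttl_times_s)
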