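"""Synthetic pose tracks, photometry recordings and cohorts with ground truth.

Every pipeline stage can be exercised against data whose answer is
known.  Three generators are provided, all pure functions of their
parameters and a seed:

* :func:`simulate_pose_track` — an arena trajectory with embedded
  immobility bouts (sub-threshold micro-motion) separated by a
  correlated random walk at locomotor speeds, rendered as a multi-
  bodypart pose track with confidence values and occasional dropouts;
* :func:`simulate_photometry` — dual-channel fluorescence with a shared
  double-exponential photobleach, Gaussian channel noise, optional point
  artifacts, and event-locked calcium transients (difference-of-
  exponentials kernel) at the schedule's stimulus onsets;
* :func:`simulate_cohort` — gamma-distributed per-animal freezing
  percentages for an OFF/ON x group design with specified
  multiplicative ON effects, feeding the statistics workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .pose import PoseTrack
from .photometry import PhotometryRecording
from .protocol import SessionSchedule

DEFAULT_BODYPART_OFFSETS_CM = {
    "nose": (1.5, 0.0),
    "body_centre": (0.0, 0.0),
    "tail_base": (-1.5, 0.0),
}


@dataclass(frozen=True)
class BehaviorGroundTruth:
    """Known immobility structure of a simulated session.

    Bouts are non-overlapping [start, end) intervals in seconds.
    ``walk_speed_cm_s`` is the median locomotion speed (log-normal
    spread ``walk_speed_sigma``); during bouts the per-frame
    displacement is half-normal with sd ``micro_sd_cm`` (0.004 cm, well
    under the 0.02 cm criterion).
    """

    bout_intervals_s: tuple[tuple[float, float], ...]
    session_duration_s: float
    walk_speed_cm_s: float = 4.0
    walk_speed_sigma: float = 0.3
    heading_sigma_rad: float = 0.5
    micro_sd_cm: float = 0.004
    dropout_prob: float = 0.005

    def __post_init__(self) -> None:
        prev_end = 0.0
        for start, end in self.bout_intervals_s:
            if start < prev_end or end <= start or end > self.session_duration_s:
                raise InvalidParameterError(
                    f"bouts must be ordered, non-overlapping and inside "
                    f"[0, {self.session_duration_s}]; offending bout ({start}, {end})"
                )
            prev_end = end
        if self.micro_sd_cm <= 0 or self.walk_speed_cm_s <= 0:
            raise InvalidParameterError("micro_sd_cm and walk_speed_cm_s must be > 0")

    @property
    def immobile_fraction(self) -> float:
        total = sum(e - s for s, e in self.bout_intervals_s)
        return total / self.session_duration_s


def make_behavior_truth(
    session_duration_s: float,
    immobile_fraction: float,
    seed: int = 0,
    mean_bout_s: float = 8.0,
    fps: float = 25.0,
    **kwargs,
) -> BehaviorGroundTruth:
    """Place random non-overlapping bouts totalling a target immobile fraction.

    Bout count is the target time divided by ``mean_bout_s``; bout and
    gap durations are drawn from a Dirichlet split and snapped to the
    frame grid, so the realized fraction matches the request to within
    a frame or two per bout.
    """
    if not 0 <= immobile_fraction <= 1:
        raise InvalidParameterError("immobile_fraction must be in [0, 1]")
    if session_duration_s <= 0:
        raise InvalidParameterError("session_duration_s must be > 0")
    if immobile_fraction == 0:
        return BehaviorGroundTruth((), session_duration_s, **kwargs)
    if immobile_fraction == 1:
        return BehaviorGroundTruth(
            ((0.0, session_duration_s),), session_duration_s, **kwargs
        )
    rng = np.random.default_rng(seed)
    target = immobile_fraction * session_duration_s
    n_bouts = max(1, int(round(target / mean_bout_s)))
    bout_lens = rng.dirichlet(np.ones(n_bouts) * 4) * target
    gap_lens = rng.dirichlet(np.ones(n_bouts + 1) * 4) * (session_duration_s - target)
    snap = lambda t: round(t * fps) / fps
    intervals = []
    t = 0.0
    for k in range(n_bouts):
        t += gap_lens[k]
        start, end = snap(t), snap(t + bout_lens[k])
        end = min(end, session_duration_s)
        if end > start:
            intervals.append((start, end))
        t += bout_lens[k]
    return BehaviorGroundTruth(tuple(intervals), session_duration_s, **kwargs)


def simulate_pose_track(
    schedule: SessionSchedule,
    truth: BehaviorGroundTruth,
    fps: float = 25.0,
    px_per_cm: float = 30.0,
    seed: int = 0,
    bodypart_offsets_cm: dict[str, tuple[float, float]] | None = None,
    arena_cm: tuple[float, float] = (30.0, 30.0),
) -> tuple[PoseTrack, BehaviorGroundTruth]:
    """Render a ground-truth immobility pattern as a pose track.

    Outside bouts the animal performs a correlated random walk
    (log-normal step lengths around ``walk_speed_cm_s``, reflected at
    the arena walls); during bouts it jitters with half-normal
    sub-threshold micro-motion.  Bodyparts sit at fixed offsets around
    the centre with small independent jitter; detections drop out
    (likelihood < 0.5, position corrupted) with ``dropout_prob`` per
    frame and bodypart.  Identical seeds give bit-identical tracks.
    """
    if truth.session_duration_s != schedule.total_duration_s:
        raise InvalidParameterError(
            "truth duration does not match the schedule's total duration"
        )
    rng = np.random.default_rng(seed)
    offsets = bodypart_offsets_cm or DEFAULT_BODYPART_OFFSETS_CM
    n_frames = int(round(schedule.total_duration_s * fps)) + 1
    n_pairs = n_frames - 1

    mid_times = (np.arange(n_pairs) + 0.5) / fps
    immobile = np.zeros(n_pairs, dtype=bool)
    for start, end in truth.bout_intervals_s:
        immobile |= (mid_times >= start) & (mid_times < end)

    # per-pair displacements
    headings = np.cumsum(rng.normal(0.0, truth.heading_sigma_rad, n_pairs))
    walk_steps = rng.lognormal(
        np.log(truth.walk_speed_cm_s / fps), truth.walk_speed_sigma, n_pairs
    )
    micro_steps = np.abs(rng.normal(0.0, truth.micro_sd_cm, n_pairs))
    micro_angles = rng.uniform(0, 2 * np.pi, n_pairs)
    steps = np.where(immobile, micro_steps, walk_steps)
    angles = np.where(immobile, micro_angles, headings)

    x = np.empty(n_frames)
    y = np.empty(n_frames)
    x[0], y[0] = arena_cm[0] / 2, arena_cm[1] / 2
    x[1:] = x[0] + np.cumsum(steps * np.cos(angles))
    y[1:] = y[0] + np.cumsum(steps * np.sin(angles))
    # reflect into the arena (period-2W triangular fold)
    for arr, size in ((x, arena_cm[0]), (y, arena_cm[1])):
        arr %= 2 * size
        over = arr > size
        arr[over] = 2 * size - arr[over]

    columns: dict[tuple[str, str], np.ndarray] = {}
    for bp, (dx, dy) in offsets.items():
        jitter = rng.normal(0.0, 0.002, (n_frames, 2))
        bx = x + dx + jitter[:, 0]
        by = y + dy + jitter[:, 1]
        conf = rng.uniform(0.95, 1.0, n_frames)
        dropped = rng.random(n_frames) < truth.dropout_prob
        conf[dropped] = rng.uniform(0.05, 0.5, int(dropped.sum()))
        bx[dropped] += rng.normal(0.0, 5.0, int(dropped.sum()))
        by[dropped] += rng.normal(0.0, 5.0, int(dropped.sum()))
        columns[(bp, "x")] = bx * px_per_cm
        columns[(bp, "y")] = by * px_per_cm
        columns[(bp, "likelihood")] = conf
    data = pd.DataFrame(columns)
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return PoseTrack(fps=fps, px_per_cm=px_per_cm, data=data), truth


@dataclass(frozen=True)
class PhotometryGroundTruth:
    """Known structure of a simulated dual-channel recording.

    Photobleaching is a double exponential shared by both channels: a
    fast component (``bleach_tau_fast_s``, mostly gone after the
    standard 60-s trim — the reason the pipeline trims) and a slow one.
    Transients are difference-of-exponentials kernels (rise 50 ms,
    decay 600 ms, peak-normalized) at ``transient_times_s`` with
    amplitudes in ΔF/F units; :func:`amplitudes_for_noise_units`
    converts "k x baseline noise sd" requests into ΔF/F using the
    analytic post-pipeline noise level.  Channel noise is white
    Gaussian (``noise_sd`` on the signal channel; control noise
    defaults to 30% of it).  Point artifacts are single-sample spikes
    at ``artifact_times_s``.
    """

    bleach_tau_fast_s: float = 20.0
    bleach_tau_slow_s: float = 3000.0
    bleach_fast_fraction: float = 0.2
    gain_signal: float = 2.0
    gain_control: float = 1.0
    transient_times_s: tuple[float, ...] = ()
    transient_amplitudes_dff: tuple[float, ...] = ()
    rise_s: float = 0.05
    decay_s: float = 0.6
    noise_sd: float = 0.02
    control_noise_sd: float | None = None
    artifact_times_s: tuple[float, ...] = ()
    artifact_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.bleach_tau_fast_s <= 0 or self.bleach_tau_slow_s <= 0:
            raise InvalidParameterError("bleach time constants must be > 0")
        if not 0 <= self.bleach_fast_fraction < 1:
            raise InvalidParameterError("bleach_fast_fraction must be in [0, 1)")
        if self.gain_signal <= 0 or self.gain_control <= 0:
            raise InvalidParameterError("channel gains must be > 0")
        if len(self.transient_times_s) != len(self.transient_amplitudes_dff):
            raise InvalidParameterError("transient times and amplitudes differ in length")
        if any(a < 0 for a in self.transient_amplitudes_dff):
            raise InvalidParameterError("transient amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not 0 < self.rise_s < self.decay_s:
            raise InvalidParameterError("need 0 < rise_s < decay_s")

    def bleach(self, t: np.ndarray) -> np.ndarray:
        f = self.bleach_fast_fraction
        return f * np.exp(-t / self.bleach_tau_fast_s) + (1 - f) * np.exp(
            -t / self.bleach_tau_slow_s
        )

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Peak-normalized difference-of-exponentials transient kernel."""
        tr, td = self.rise_s, self.decay_s
        t_peak = np.log(td / tr) * tr * td / (td - tr)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        k = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / td) - np.exp(-np.clip(t, 0, None) / tr), 0.0)
        return k / peak

    def _control_noise(self) -> float:
        return 0.3 * self.noise_sd if self.control_noise_sd is None else self.control_noise_sd

    def expected_dff_noise_sd(self, trim_s: float, duration_s: float) -> float:
        """Analytic rms noise sd of the post-pipeline ΔF/F trace.

        Propagates both channels' noise through the isosbestic fit
        (fitted control ≈ gain_signal x bleach) and averages the
        time-varying variance over the trimmed trace.
        """
        t = np.linspace(trim_s, duration_s, 512)
        total_var = self.noise_sd**2 + (
            self.gain_signal / self.gain_control * self._control_noise()
        ) ** 2
        return float(np.sqrt(np.mean(total_var / (self.gain_signal * self.bleach(t)) ** 2)))

    def with_amplitudes_in_noise_units(
        self,
        amplitudes_sd: tuple[float, ...],
        times_s: tuple[float, ...],
        trim_s: float = 60.0,
        duration_s: float | None = None,
    ) -> "PhotometryGroundTruth":
        """Return a truth whose transient peaks are k x the baseline noise sd.

        ``duration_s`` defaults to 1 s past the last transient plus the
        decay tail; pass the session duration for exactness.
        """
        if duration_s is None:
            duration_s = max(times_s) + 10.0 if times_s else trim_s + 60.0
        sd = self.expected_dff_noise_sd(trim_s, duration_s)
        return replace(
            self,
            transient_times_s=tuple(times_s),
            transient_amplitudes_dff=tuple(a * sd for a in amplitudes_sd),
        )


def simulate_photometry(
    schedule: SessionSchedule,
    truth: PhotometryGroundTruth,
    fs: float = 100.0,
    seed: int = 0,
) -> tuple[PhotometryRecording, PhotometryGroundTruth]:
    """Render a ground-truth structure as a dual-channel recording.

    Both channels carry the shared bleach scaled by their gain plus
    white noise; the signal channel additionally carries the calcium
    transients as fractional (ΔF/F-unit) modulations of its bleach
    baseline.  TTL pulses mark the schedule's CS onsets.  Identical
    seeds give bit-identical recordings.
    """
    if fs < 20:
        raise InvalidParameterError(f"fs must be >= 20 samples/s, got {fs}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, schedule.total_duration_s, 1.0 / fs)
    bleach = truth.bleach(t)
    cn = truth._control_noise()
    f_control = truth.gain_control * bleach
    if cn > 0:
        f_control = f_control + rng.normal(0.0, cn, len(t))
    f_signal = truth.gain_signal * bleach.copy()
    for onset, amp in zip(truth.transient_times_s, truth.transient_amplitudes_dff):
        f_signal = f_signal + amp * truth.gain_signal * bleach * truth.kernel(t - onset)
    if truth.noise_sd > 0:
        f_signal = f_signal + rng.normal(0.0, truth.noise_sd, len(t))
    for at in truth.artifact_times_s:
        idx = int(round(at * fs))
        if 0 <= idx < len(t):
            f_signal[idx] += truth.artifact_amplitude
            f_control[idx] += truth.artifact_amplitude
    ttl = np.array([ev.onset_s for ev in schedule.events if ev.modality != "shock"])
    return PhotometryRecording(t, f_signal, f_control, ttl), truth


def simulate_cohort(
    n_per_group: dict[str, int] | None = None,
    on_effect: dict[str, float] | None = None,
    off_mean: float = 15.0,
    shape: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Gamma-distributed freezing percentages for an OFF/ON x group design.

    Defaults mirror the probe-test design: three groups of 12 animals;
    the paired group freezes 2.5x more during the ON period while the
    unpaired and no-shock groups show no ON effect.  Values are drawn
    independently per animal x epoch from a gamma with the given shape
    (mean ``off_mean`` OFF, ``effect * off_mean`` ON).  Returns a tidy
    table (animal, group, epoch, value) and the ground-truth dict.
    """
    n_per_group = n_per_group or {"paired": 12, "unpaired": 12, "no_shock": 12}
    on_effect = on_effect or {"paired": 2.5, "unpaired": 1.0, "no_shock": 1.0}
    if any(n <= 0 for n in n_per_group.values()):
        raise InvalidParameterError("group sizes must be positive")
    if not np.isfinite(shape) or shape <= 0:
        raise InvalidParameterError(
            "shape must be positive and finite (zero-variance cohorts are not simulable)"
        )
    if off_mean <= 0 or any(e <= 0 for e in on_effect.values()):
        raise InvalidParameterError("off_mean and ON effects must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    animal = 0
    for group, n in n_per_group.items():
        effect = on_effect.get(group, 1.0)
        for _ in range(n):
            animal += 1
            for epoch, mean in (("OFF", off_mean), ("ON", effect * off_mean)):
                rows.append(
                    {
                        "animal_id": f"m{animal:03d}",
                        "group": group,
                        "epoch": epoch,
                        "value": rng.gamma(shape, mean / shape),
                    }
                )
    truth = {
        "off_mean": off_mean,
        "shape": shape,
        "on_effect": dict(on_effect),
        "n_per_group": dict(n_per_group),
    }
    return pd.DataFrame(rows), truth
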