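"""Freezing quantification from pose-estimation tracks.

The behavioral readout of fear in this task is freezing (immobility).
A track of per-frame bodypart coordinates (the DeepLabCut CSV dialect:
three header rows — scorer / bodyparts / coords — with x, y, likelihood
triplets) is reduced to a single reference trajectory in cm, per-pair
speeds are computed as the Euclidean distance between consecutive
frames times the frame rate, and a frame pair is scored as freezing
when its displacement is strictly below a threshold — 0.02 cm per pair
of frames at 25 fps, i.e. a speed strictly below 0.5 cm/s.

Summaries follow the task's reporting conventions: percent time
freezing per OFF/ON epoch and binned time courses (10-s bins by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    InvalidParameterError,
    ParseError,
    TooShortError,
    UndefinedEpochError,
    UnusableTrackError,
)
from .protocol import Epoch


@dataclass(frozen=True)
class FreezingParams:
    """Parameters of the immobility criterion.

    displacement_threshold_cm
        Maximum frame-to-frame displacement (cm) still counted as
        freezing; strict inequality.  0.02 cm at 25 fps corresponds to
        the 0.5 cm/s speed criterion.
    min_confidence
        Pose-estimation likelihood below which a point is excluded and
        bridged by linear interpolation.
    reference_point
        Bodypart used as the animal's position, or "centroid" for the
        mean of all confident bodyparts.
    min_bout_s
        Optional bout smoothing: freezing runs shorter than this are
        relabelled as movement.  0 disables smoothing (the default:
        classification is per frame pair, exactly as the criterion is
        stated).
    """

    displacement_threshold_cm: float = 0.02
    min_confidence: float = 0.9
    reference_point: str = "centroid"
    min_bout_s: float = 0.0

    def __post_init__(self) -> None:
        if self.displacement_threshold_cm <= 0:
            raise InvalidParameterError("displacement_threshold_cm must be > 0")
        if not 0 <= self.min_confidence <= 1:
            raise InvalidParameterError("min_confidence must be in [0, 1]")
        if self.min_bout_s < 0:
            raise InvalidParameterError("min_bout_s must be >= 0")

    def speed_threshold_cm_s(self, fps: float) -> float:
        """Equivalent speed criterion: displacement threshold x fps."""
        return self.displacement_threshold_cm * fps


@dataclass(frozen=True)
class PoseTrack:
    """Per-frame bodypart coordinates with detection confidence.

    ``data`` has DeepLabCut-style two-level columns (bodypart, coord)
    with coords x, y (pixels) and likelihood in [0, 1]; one row per
    frame.
    """

    fps: float
    px_per_cm: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidParameterError(f"fps must be > 0, got {self.fps}")
        if self.px_per_cm <= 0:
            raise InvalidParameterError(f"px_per_cm must be > 0, got {self.px_per_cm}")
        for bp in self.bodyparts:
            cols = set(self.data[bp].columns)
            if cols != {"x", "y", "likelihood"}:
                raise InvalidParameterError(
                    f"bodypart {bp!r} has columns {sorted(cols)}, "
                    "expected x, y, likelihood"
                )

    @property
    def bodyparts(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class FreezingSeries:
    """Per-frame-pair speeds and freezing labels.

    A track of n frames yields n-1 pairs; ``pair_times_s`` holds each
    pair's midpoint time, used for epoch membership.
    """

    pair_times_s: np.ndarray
    speeds_cm_s: np.ndarray
    is_freezing: np.ndarray
    fps: float
    params: FreezingParams = field(default_factory=FreezingParams)

    def __post_init__(self) -> None:
        n = len(self.pair_times_s)
        if len(self.speeds_cm_s) != n or len(self.is_freezing) != n:
            raise AlignmentError("pair_times_s, speeds_cm_s, is_freezing lengths differ")
        if np.any(np.asarray(self.speeds_cm_s) < 0):
            raise InvalidParameterError("speeds must be >= 0")

    def percent_freezing_total(self) -> float:
        return 100.0 * float(np.mean(self.is_freezing))


def read_pose_csv(path, fps: float, px_per_cm: float) -> PoseTrack:
    """Read a DeepLabCut-dialect pose CSV.

    Expects three header rows (scorer / bodyparts / coords) and x, y,
    likelihood triplets per bodypart.  Coordinates are kept in pixels;
    conversion to cm happens in :func:`reference_trajectory`.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: not a three-header pose CSV ({exc})") from exc
    if df.columns.nlevels != 3:
        raise ParseError(f"{path}: expected 3 header rows, got {df.columns.nlevels}")
    # Drop the scorer level; keep (bodypart, coord).
    df.columns = pd.MultiIndex.from_arrays(
        [df.columns.get_level_values(1), df.columns.get_level_values(2)]
    )
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(0)))
    for bp in bodyparts:
        coords = set(df[bp].columns)
        if coords != {"x", "y", "likelihood"}:
            raise ParseError(
                f"{path}: bodypart {bp!r} has coords {sorted(coords)}, "
                "expected x, y, likelihood"
            )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad_rows = numeric.index[numeric.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: non-numeric cells in rows {bad_rows[:5]}")
    return PoseTrack(fps=fps, px_per_cm=px_per_cm, data=numeric)


def write_pose_csv(track: PoseTrack, path, scorer: str = "spckit") -> None:
    """Write a track back to the three-header pose CSV dialect."""
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_arrays(
        [
            [scorer] * len(df.columns),
            df.columns.get_level_values(0),
            df.columns.get_level_values(1),
        ],
        names=["scorer", "bodyparts", "coords"],
    )
    df.to_csv(path, index_label=None)


def _interpolate_gaps(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate invalid samples; extend edges with nearest valid."""
    out = values.astype(float).copy()
    idx = np.arange(len(values))
    out[~valid] = np.interp(idx[~valid], idx[valid], values[valid])
    return out


def reference_trajectory(track: PoseTrack, params: FreezingParams | None = None) -> np.ndarray:
    """Reduce a track to one (x_cm, y_cm) position per frame.

    Uses the configured bodypart, or the centroid of bodyparts.  Each
    bodypart's low-confidence frames are bridged first by linear
    interpolation along that bodypart's own trajectory (nearest valid
    frame at the edges), and the centroid averages the repaired parts.
    Per-part interpolation keeps the centroid from jumping when a single
    detection drops out.  Bodyparts confident in fewer than half the
    frames are excluded with a log message; none usable raises
    :class:`UnusableTrackError`.
    """
    import logging

    params = params or FreezingParams()
    if params.reference_point == "centroid":
        parts = track.bodyparts
    else:
        if params.reference_point not in track.bodyparts:
            raise InvalidParameterError(
                f"reference bodypart {params.reference_point!r} not in track "
                f"(has {track.bodyparts})"
            )
        parts = [params.reference_point]

    repaired_x, repaired_y = [], []
    for bp in parts:
        conf = track.data[(bp, "likelihood")].to_numpy(float)
        valid = conf >= params.min_confidence
        if valid.sum() < 0.5 * len(valid):
            logging.getLogger(__name__).info(
                "reference_trajectory: excluding %r (confident in %.0f%% of frames)",
                bp,
                100 * valid.mean(),
            )
            continue
        repaired_x.append(
            _interpolate_gaps(track.data[(bp, "x")].to_numpy(float), valid)
        )
        repaired_y.append(
            _interpolate_gaps(track.data[(bp, "y")].to_numpy(float), valid)
        )
    if not repaired_x:
        raise UnusableTrackError(
            "no bodypart exceeds the confidence cutoff in at least half the frames"
        )
    x = np.mean(repaired_x, axis=0)
    y = np.mean(repaired_y, axis=0)
    return np.column_stack([x, y]) / track.px_per_cm


def compute_speed(trajectory_cm: np.ndarray, fps: float) -> np.ndarray:
    """Per-pair speed (cm/s): Euclidean displacement between consecutive frames x fps."""
    traj = np.asarray(trajectory_cm, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise InvalidParameterError("trajectory must be an (n, 2) array of cm positions")
    if len(traj) < 2:
        raise TooShortError("need at least 2 frames to compute a speed")
    disp = np.hypot(np.diff(traj[:, 0]), np.diff(traj[:, 1]))
    return disp * fps


def _suppress_short_bouts(is_freezing: np.ndarray, min_pairs: int) -> np.ndarray:
    out = is_freezing.copy()
    n = len(out)
    i = 0
    while i < n:
        if out[i]:
            j = i
            while j < n and out[j]:
                j += 1
            if j - i < min_pairs:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


def classify_freezing(
    speeds_cm_s: np.ndarray, params: FreezingParams, fps: float
) -> FreezingSeries:
    """Label each frame pair: freezing iff speed strictly below threshold.

    The threshold is ``displacement_threshold_cm * fps`` (0.5 cm/s at the
    defaults); a pair moving at exactly the threshold speed is *not*
    freezing.
    """
    speeds = np.asarray(speeds_cm_s, dtype=float)
    threshold = params.speed_threshold_cm_s(fps)
    is_freezing = speeds < threshold
    if params.min_bout_s > 0:
        is_freezing = _suppress_short_bouts(
            is_freezing, int(np.ceil(params.min_bout_s * fps))
        )
    pair_times = (np.arange(len(speeds)) + 0.5) / fps
    return FreezingSeries(pair_times, speeds, is_freezing, fps, params)


def score_track(
    track: PoseTrack, params: FreezingParams | None = None
) -> FreezingSeries:
    """Full per-track pipeline: reference trajectory -> speeds -> labels."""
    params = params or FreezingParams()
    traj = reference_trajectory(track, params)
    speeds = compute_speed(traj, track.fps)
    return classify_freezing(speeds, params, track.fps)


def percent_freezing(series: FreezingSeries, epoch: Epoch) -> float:
    """Percent of frame pairs labelled freezing whose midpoint lies in the epoch."""
    mask = (series.pair_times_s >= epoch.start_s) & (series.pair_times_s < epoch.end_s)
    if not mask.any():
        raise UndefinedEpochError(
            f"epoch {epoch.label!r} [{epoch.start_s}, {epoch.end_s}) contains no frame pairs"
        )
    return 100.0 * float(np.mean(series.is_freezing[mask]))


def binned_freezing(
    series: FreezingSeries, bin_s: float = 10.0, total_duration_s: float | None = None
) -> pd.DataFrame:
    """Percent freezing per half-open time bin [k*bin_s, (k+1)*bin_s).

    Returns a frame with bin_start_s, bin_end_s, percent_freezing,
    n_pairs and is_partial.  Bins with no pairs get NaN (missing), never
    0; a trailing partial bin is kept and flagged.
    """
    if bin_s <= 0:
        raise InvalidParameterError(f"bin_s must be > 0, got {bin_s}")
    end = total_duration_s
    if end is None:
        end = float(series.pair_times_s[-1]) + 0.5 / series.fps if len(series.pair_times_s) else 0.0
    n_bins = int(np.ceil(end / bin_s))
    idx = np.floor(series.pair_times_s / bin_s).astype(int)
    rows = []
    for k in range(n_bins):
        mask = idx == k
        n = int(mask.sum())
        rows.append(
            {
                "bin_start_s": k * bin_s,
                "bin_end_s": (k + 1) * bin_s,
                "percent_freezing": 100.0 * float(np.mean(series.is_freezing[mask]))
                if n
                else np.nan,
                "n_pairs": n,
                "is_partial": (k + 1) * bin_s > end,
            }
        )
    return pd.DataFrame(rows)


def series_to_frame(series: FreezingSeries) -> pd.DataFrame:
    """Tidy per-pair table (pair_time_s, speed_cm_s, is_freezing)."""
    return pd.DataFrame(
        {
            "pair_time_s": series.pair_times_s,
            "speed_cm_s": series.speeds_cm_s,
            "is_freezing": series.is_freezing,
        }
    )


def compare_with_reference(
    candidate: FreezingSeries,
    reference: "FreezingSeries | np.ndarray",
    bin_s: float = 10.0,
) -> dict:
    """Concordance between this scorer and an external freezing reference.

    The reference is another scorer's per-pair boolean labels on the
    same clock (a :class:`FreezingSeries` or a boolean array of equal
    length).  Reports the frame-pair agreement fraction and the Pearson
    correlation of binned freezing percentages — the two statistics a
    validation against manual counts or another scoring tool would use.
    """
    ref_labels = reference.is_freezing if isinstance(reference, FreezingSeries) else np.asarray(reference, dtype=bool)
    if len(ref_labels) != len(candidate.is_freezing):
        raise AlignmentError(
            f"candidate has {len(candidate.is_freezing)} pairs, reference {len(ref_labels)}"
        )
    agreement = float(np.mean(candidate.is_freezing == ref_labels))
    ref_series = FreezingSeries(
        candidate.pair_times_s, candidate.speeds_cm_s, ref_labels, candidate.fps, candidate.params
    )
    a = binned_freezing(candidate, bin_s)["percent_freezing"].to_numpy()
    b = binned_freezing(ref_series, bin_s)["percent_freezing"].to_numpy()
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) >= 2 and np.std(a) > 0 and np.std(b) > 0:
        r = float(np.corrcoef(a, b)[0, 1])
    else:
        r = np.nan
    return {"pearson_r_binned": r, "agreement": agreement, "bin_s": bin_s}
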