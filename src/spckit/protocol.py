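"""Session schedules for the light-tone sensory preconditioning task.

A session is modelled as an ordered list of epochs (OFF / ON / ITI /
baseline) that tile the session without gaps, plus a list of stimulus
events (light, tone, simultaneous light+tone, footshock).  Builders
construct the canonical phases of the task:

* habituation — a single long OFF epoch;
* preconditioning — OFF, then n simultaneous light+tone presentations
  separated by inter-trial intervals, then a final OFF;
* conditioning — OFF, then n light presentations each co-terminating
  with a footshock, then a final OFF;
* probe test — an OFF period followed by a continuous ON period with a
  single stimulus (the tone probes mediated learning, the light direct
  learning).

All epoch boundaries are half-open ``[start, end)`` so that every
instant of the session belongs to exactly one epoch.  Epoch tiling is
validated with exact rational arithmetic on the stored floats, so the
"durations sum to the total" invariant holds bit-exactly, not merely to
a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, OutOfRangeError

MODALITIES = ("light", "tone", "light+tone", "shock")
EPOCH_KINDS = ("OFF", "ON", "ITI", "baseline")
PHASES = ("habituation", "preconditioning", "conditioning", "probe1", "probe2")
GROUPS = ("paired", "unpaired", "no_shock")


@dataclass(frozen=True)
class StimulusEvent:
    """A timed stimulus presentation within a session."""

    onset_s: float
    duration_s: float
    modality: str

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise InvalidParameterError(f"event onset must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise InvalidParameterError(
                f"event duration must be > 0, got {self.duration_s}"
            )
        if self.modality not in MODALITIES:
            raise InvalidParameterError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class Epoch:
    """A half-open interval [start_s, end_s) with a label and a kind."""

    label: str
    kind: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise InvalidParameterError(
                f"unknown epoch kind {self.kind!r}; expected one of {EPOCH_KINDS}"
            )
        if not self.end_s > self.start_s:
            raise InvalidParameterError(
                f"epoch {self.label!r}: end ({self.end_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class SessionSchedule:
    """Epochs and stimulus events of one behavioral session.

    Invariants enforced at construction: epochs tile ``[0,
    total_duration_s]`` without gaps or overlaps (checked in exact
    rational arithmetic), per-modality events do not overlap, and every
    event lies inside an ON epoch.
    """

    phase: str
    group: str
    epochs: tuple[Epoch, ...]
    events: tuple[StimulusEvent, ...]
    total_duration_s: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise InvalidParameterError(f"unknown phase {self.phase!r}")
        if self.group not in GROUPS:
            raise InvalidParameterError(f"unknown group {self.group!r}")
        if not self.epochs:
            raise InvalidParameterError("a schedule needs at least one epoch")
        object.__setattr__(self, "epochs", tuple(self.epochs))
        object.__setattr__(self, "events", tuple(self.events))
        self._validate_tiling()
        self._validate_events()

    def _validate_tiling(self) -> None:
        if self.epochs[0].start_s != 0.0:
            raise InvalidParameterError("first epoch must start at 0 s")
        for prev, nxt in zip(self.epochs, self.epochs[1:]):
            if prev.end_s != nxt.start_s:
                raise InvalidParameterError(
                    f"epochs {prev.label!r} and {nxt.label!r} do not tile: "
                    f"{prev.end_s} != {nxt.start_s}"
                )
        # Exact rational check: with tiling, the duration sum telescopes.
        total = sum(
            (Fraction(e.end_s) - Fraction(e.start_s) for e in self.epochs),
            Fraction(0),
        )
        if total != Fraction(self.total_duration_s):
            raise InvalidParameterError(
                f"epoch durations sum to {float(total)}, not total_duration_s="
                f"{self.total_duration_s}"
            )

    def _validate_events(self) -> None:
        by_modality: dict[str, list[StimulusEvent]] = {}
        for ev in self.events:
            by_modality.setdefault(ev.modality, []).append(ev)
            on_epochs = [e for e in self.epochs if e.kind == "ON"]
            if not any(
                e.start_s <= ev.onset_s and ev.offset_s <= e.end_s for e in on_epochs
            ):
                raise InvalidParameterError(
                    f"event {ev.modality!r} at {ev.onset_s} s does not lie inside an ON epoch"
                )
        for modality, evs in by_modality.items():
            evs = sorted(evs, key=lambda e: e.onset_s)
            for a, b in zip(evs, evs[1:]):
                if b.onset_s < a.offset_s:
                    raise InvalidParameterError(
                        f"overlapping {modality!r} events at {a.onset_s} and {b.onset_s} s"
                    )

    # -- queries ---------------------------------------------------------

    def epoch_of(self, t: float) -> Epoch:
        """Return the unique epoch containing time ``t`` (half-open)."""
        if not 0 <= t < self.total_duration_s:
            raise OutOfRangeError(
                f"t={t} s outside session [0, {self.total_duration_s})"
            )
        for epoch in self.epochs:
            if epoch.contains(t):
                return epoch
        raise OutOfRangeError(f"no epoch contains t={t} s")  # pragma: no cover

    def epochs_of_kind(self, kind: str) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if e.kind == kind)

    def event_onsets(self, modality: str | None = None) -> np.ndarray:
        """Onset times (s) of events, optionally restricted to one modality."""
        return np.array(
            [ev.onset_s for ev in self.events if modality is None or ev.modality == modality]
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "group": self.group,
            "total_duration_s": self.total_duration_s,
            "epochs": [
                {"label": e.label, "kind": e.kind, "start_s": e.start_s, "end_s": e.end_s}
                for e in self.epochs
            ],
            "events": [
                {"onset_s": ev.onset_s, "duration_s": ev.duration_s, "modality": ev.modality}
                for ev in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionSchedule":
        return cls(
            phase=d["phase"],
            group=d["group"],
            epochs=tuple(Epoch(**e) for e in d["epochs"]),
            events=tuple(StimulusEvent(**ev) for ev in d["events"]),
            total_duration_s=float(d["total_duration_s"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SessionSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_event_table(self) -> pd.DataFrame:
        """Flat event table (onset_s, duration_s, modality, epoch_label)."""
        rows = [
            {
                "onset_s": ev.onset_s,
                "duration_s": ev.duration_s,
                "modality": ev.modality,
                "epoch_label": self.epoch_of(ev.onset_s).label,
            }
            for ev in self.events
        ]
        return pd.DataFrame(rows, columns=["onset_s", "duration_s", "modality", "epoch_label"])


def epoch_labels(schedule: SessionSchedule, times_s: Sequence[float]) -> np.ndarray:
    """Label each time point with the kind of the epoch containing it.

    Boundaries are half-open, so a sample exactly at an epoch boundary
    belongs to the later epoch.  Times outside ``[0, total_duration_s)``
    raise :class:`OutOfRangeError`.
    """
    times = np.asarray(times_s, dtype=float)
    if times.size and (times.min() < 0 or times.max() >= schedule.total_duration_s):
        bad = times[(times < 0) | (times >= schedule.total_duration_s)][0]
        raise OutOfRangeError(
            f"time {bad} s outside session [0, {schedule.total_duration_s})"
        )
    starts = np.array([e.start_s for e in schedule.epochs])
    kinds = np.array([e.kind for e in schedule.epochs])
    idx = np.searchsorted(starts, times, side="right") - 1
    return kinds[idx]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise InvalidParameterError(f"{name} must be > 0, got {value}")


def build_habituation_schedule(duration_s: float = 1200.0) -> SessionSchedule:
    """A single OFF epoch; the task's 20-min habituation by default."""
    _check_positive(duration_s=duration_s)
    return SessionSchedule(
        phase="habituation",
        group="paired",
        epochs=(Epoch("habituation", "OFF", 0.0, duration_s),),
        events=(),
        total_duration_s=duration_s,
    )


def build_preconditioning_schedule(
    n_trials: int = 5,
    cs_duration_s: float = 30.0,
    iti_s: float = 30.0,
    initial_off_s: float = 180.0,
    final_off_s: float = 60.0,
    group: str = "paired",
    unpaired_modality: str = "light",
) -> SessionSchedule:
    """Preconditioning session: OFF, n CS presentations with ITIs, final OFF.

    Paired and no-shock groups receive simultaneous light+tone events; an
    unpaired session presents a single modality (``unpaired_modality``),
    with the across-session alternation left to the caller (see
    :func:`unpaired_session_modalities`).  With n >= 1 the total duration
    is ``initial_off + n*cs + (n-1)*iti + final_off``; the task defaults
    (5 x 30 s CS, 30 s ITI, 3-min initial and 1-min final OFF) give the
    canonical 510-s session.
    """
    if n_trials < 0:
        raise InvalidParameterError(f"n_trials must be >= 0, got {n_trials}")
    _check_positive(
        cs_duration_s=cs_duration_s,
        iti_s=iti_s,
        initial_off_s=initial_off_s,
        final_off_s=final_off_s,
    )
    if group not in GROUPS:
        raise InvalidParameterError(f"unknown group {group!r}")
    modality = "light+tone" if group in ("paired", "no_shock") else unpaired_modality
    if modality not in ("light", "tone", "light+tone"):
        raise InvalidParameterError(f"unsupported CS modality {modality!r}")

    epochs: list[Epoch] = [Epoch("OFF_pre", "OFF", 0.0, initial_off_s)]
    events: list[StimulusEvent] = []
    t = initial_off_s
    for k in range(n_trials):
        epochs.append(Epoch(f"trial{k + 1}", "ON", t, t + cs_duration_s))
        events.append(StimulusEvent(t, cs_duration_s, modality))
        t += cs_duration_s
        if k < n_trials - 1:
            epochs.append(Epoch(f"iti{k + 1}", "ITI", t, t + iti_s))
            t += iti_s
    epochs.append(Epoch("OFF_post", "OFF", t, t + final_off_s))
    t += final_off_s
    return SessionSchedule("preconditioning", group, tuple(epochs), tuple(events), t)


def build_conditioning_schedule(
    n_trials: int = 5,
    cs_duration_s: float = 10.0,
    shock_duration_s: float = 2.0,
    iti_s: float = 60.0,
    initial_off_s: float = 180.0,
    final_off_s: float = 60.0,
    group: str = "paired",
) -> SessionSchedule:
    """Conditioning session: light CS co-terminating with a footshock.

    Each shock starts ``cs_duration_s - shock_duration_s`` after its CS
    onset so the two end together.  The no-shock group receives the same
    light presentations with no shock events.
    """
    if n_trials < 0:
        raise InvalidParameterError(f"n_trials must be >= 0, got {n_trials}")
    _check_positive(
        cs_duration_s=cs_duration_s,
        shock_duration_s=shock_duration_s,
        iti_s=iti_s,
        initial_off_s=initial_off_s,
        final_off_s=final_off_s,
    )
    if shock_duration_s > cs_duration_s:
        raise InvalidParameterError(
            f"shock ({shock_duration_s} s) cannot outlast the CS ({cs_duration_s} s)"
        )
    if group not in GROUPS:
        raise InvalidParameterError(f"unknown group {group!r}")

    epochs: list[Epoch] = [Epoch("OFF_pre", "OFF", 0.0, initial_off_s)]
    events: list[StimulusEvent] = []
    t = initial_off_s
    for k in range(n_trials):
        epochs.append(Epoch(f"trial{k + 1}", "ON", t, t + cs_duration_s))
        events.append(StimulusEvent(t, cs_duration_s, "light"))
        if group != "no_shock":
            events.append(
                StimulusEvent(t + cs_duration_s - shock_duration_s, shock_duration_s, "shock")
            )
        t += cs_duration_s
        if k < n_trials - 1:
            epochs.append(Epoch(f"iti{k + 1}", "ITI", t, t + iti_s))
            t += iti_s
    epochs.append(Epoch("OFF_post", "OFF", t, t + final_off_s))
    t += final_off_s
    return SessionSchedule("conditioning", group, tuple(epochs), tuple(events), t)


def build_probe_schedule(
    off_s: float = 180.0,
    on_s: float = 180.0,
    modality: str = "tone",
    group: str = "paired",
) -> SessionSchedule:
    """Probe test: an OFF period then a continuous single-stimulus ON period.

    The tone probe (probe 1) reads out mediated learning, the light probe
    (probe 2) direct learning.  Defaults give the 6-min session.
    """
    _check_positive(off_s=off_s, on_s=on_s)
    if modality not in ("tone", "light"):
        raise InvalidParameterError(f"probe modality must be tone or light, got {modality!r}")
    phase = "probe1" if modality == "tone" else "probe2"
    epochs = (
        Epoch("OFF", "OFF", 0.0, off_s),
        Epoch("ON", "ON", off_s, off_s + on_s),
    )
    events = (StimulusEvent(off_s, on_s, modality),)
    return SessionSchedule(phase, group, epochs, events, off_s + on_s)


def unpaired_session_modalities(
    n_sessions: int = 6, seed: int | None = 0
) -> list[str]:
    """Pseudo-random light/tone order for an unpaired group's sessions.

    Balanced: each modality appears ``n_sessions // 2`` times (the extra
    session of an odd count is assigned randomly).  Deterministic for a
    given seed.
    """
    if n_sessions < 0:
        raise InvalidParameterError("n_sessions must be >= 0")
    rng = np.random.default_rng(seed)
    seq = ["light", "tone"] * (n_sessions // 2)
    if n_sessions % 2:
        seq.append(str(rng.choice(["light", "tone"])))
    rng.shuffle(seq)
    return list(seq)
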