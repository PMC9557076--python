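"""Per-phase inversion-time planning for a prospectively triggered
Look-Locker FLASH acquisition.

The acquisition repeats a Look-Locker experiment several times, each time
shifting the inversion pulse by a different offset relative to the ECG
R-wave.  Because the recovery to the pulsed steady state spans
``recovery_beats`` heart beats, every inversion contributes
``recovery_beats`` samples per cardiac phase (one per beat), so each phase
ends up with ``recovery_beats * n_offsets`` inversion times.

Dummy excitation pulses fill the gap between the end of the acquisition
window and the next R-wave so the pulsed recovery is never interrupted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SequenceParams",
    "CardiacTiming",
    "AcquisitionPlan",
    "default_offsets",
    "plan_acquisition",
    "dummy_pulse_counts",
]


class InvalidParameterError(ValueError):
    """A sequence/timing parameter is outside its valid range."""


class NoPhasesError(ValueError):
    """The acquisition window is too short to contain a single phase."""


def default_offsets(rr_ms: float, n_offsets: int = 3) -> tuple[float, ...]:
    """Evenly spaced inversion-pulse offsets ``{0, RR/n, 2 RR/n, ...}``.

    The even spacing maximizes the spread of inversion times realized per
    cardiac phase.
    """
    if n_offsets < 1:
        raise InvalidParameterError("n_offsets must be >= 1")
    return tuple(rr_ms * k / n_offsets for k in range(n_offsets))


@dataclass(frozen=True)
class SequenceParams:
    """Sequence parameters of the phase-resolved Look-Locker FLASH scan.

    ``offset_times_ms`` may be ``None``, in which case three evenly spaced
    offsets over the (minimum) R-R interval are filled in at planning time.
    """

    tr_ms: float
    flip_deg: float
    lines_per_segment: int = 1
    offset_times_ms: tuple[float, ...] | None = None
    acq_window_fraction: float = 0.9
    inv_efficiency: float = 1.0
    recovery_beats: int = 2

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise InvalidParameterError("tr_ms must be > 0")
        if not (0 < self.flip_deg < 90):
            raise InvalidParameterError("flip_deg must be in (0, 90)")
        if self.lines_per_segment < 1:
            raise InvalidParameterError("lines_per_segment must be >= 1")
        if not (0 < self.acq_window_fraction <= 1):
            raise InvalidParameterError("acq_window_fraction must be in (0, 1]")
        if not (0 <= self.inv_efficiency <= 1):
            raise InvalidParameterError("inv_efficiency must be in [0, 1]")
        if self.recovery_beats < 1:
            raise InvalidParameterError("recovery_beats must be >= 1")
        if self.offset_times_ms is not None:
            object.__setattr__(
                self, "offset_times_ms", tuple(float(t) for t in self.offset_times_ms)
            )

    @property
    def n_offsets(self) -> int:
        return 3 if self.offset_times_ms is None else len(self.offset_times_ms)

    def resolved_offsets(self, rr_ms: float) -> tuple[float, ...]:
        """Concrete offsets for a given R-R interval, validated to [0, RR)."""
        offs = (
            default_offsets(rr_ms, 3)
            if self.offset_times_ms is None
            else self.offset_times_ms
        )
        for t in offs:
            if not (0 <= t < rr_ms):
                raise InvalidParameterError(
                    f"inversion offset {t} ms outside [0, {rr_ms}) ms"
                )
        return offs


@dataclass(frozen=True)
class CardiacTiming:
    """ECG timing: R-R interval series and the temporal resolution.

    ``rr_ms`` may hold a single value (constant heart rate) or a series of
    measured beat durations; the series is cycled over the beats of the
    acquisition.
    """

    rr_ms: tuple[float, ...]
    phase_duration_ms: float

    def __post_init__(self) -> None:
        rr = tuple(float(v) for v in (
            (self.rr_ms,) if np.isscalar(self.rr_ms) else self.rr_ms
        ))
        if len(rr) == 0 or any(v <= 0 for v in rr):
            raise InvalidParameterError("all rr_ms must be > 0")
        if self.phase_duration_ms <= 0:
            raise InvalidParameterError("phase_duration_ms must be > 0")
        object.__setattr__(self, "rr_ms", rr)

    @classmethod
    def from_heart_rate(
        cls, bpm: float, phase_duration_ms: float
    ) -> "CardiacTiming":
        return cls(rr_ms=(60000.0 / bpm,), phase_duration_ms=phase_duration_ms)

    @property
    def min_rr_ms(self) -> float:
        return min(self.rr_ms)

    def rr_of_beat(self, beat: int) -> float:
        return self.rr_ms[beat % len(self.rr_ms)]

    def n_phases(self, acq_window_fraction: float) -> int:
        n = math.floor(
            acq_window_fraction * self.min_rr_ms / self.phase_duration_ms
        )
        if n < 1:
            raise NoPhasesError(
                "phase_duration_ms exceeds the acquisition window"
            )
        return n


@dataclass
class AcquisitionPlan:
    """The realized inversion-time table of one scan.

    Arrays are indexed ``[phase, sample]`` with samples sorted by ascending
    inversion time within each phase; ``offset_index`` and ``beat_index``
    carry the provenance of each sample.
    """

    ti_ms: np.ndarray           # (n_phases, n_ti) float, sorted ascending per phase
    offset_index: np.ndarray    # (n_phases, n_ti) int
    beat_index: np.ndarray      # (n_phases, n_ti) int, recovery beat of the sample
    phase_centers_ms: np.ndarray  # (n_phases,)
    dummy_counts: np.ndarray    # per distinct beat in the R-R series
    offset_times_ms: tuple[float, ...] = field(default_factory=tuple)
    rr_ms: tuple[float, ...] = field(default_factory=tuple)

    @property
    def n_phases(self) -> int:
        return self.ti_ms.shape[0]

    @property
    def n_ti(self) -> int:
        return self.ti_ms.shape[1]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        n_p, n_t = self.ti_ms.shape
        return pd.DataFrame(
            {
                "phase_index": np.repeat(np.arange(n_p), n_t),
                "offset_index": self.offset_index.ravel(),
                "beat_index": self.beat_index.ravel(),
                "ti_ms": self.ti_ms.ravel(),
            }
        )

    @classmethod
    def from_csv(cls, path) -> "AcquisitionPlan":
        df = pd.read_csv(path)
        required = {"phase_index", "offset_index", "beat_index", "ti_ms"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"plan CSV missing columns: {sorted(missing)}")
        n_p = int(df["phase_index"].max()) + 1
        counts = df.groupby("phase_index").size()
        if counts.nunique() != 1 or len(counts) != n_p:
            raise ValueError("plan CSV has unequal TI counts across phases")
        n_t = int(counts.iloc[0])
        df = df.sort_values(["phase_index", "ti_ms"], kind="stable")
        shape = (n_p, n_t)
        return cls(
            ti_ms=df["ti_ms"].to_numpy(float).reshape(shape),
            offset_index=df["offset_index"].to_numpy(int).reshape(shape),
            beat_index=df["beat_index"].to_numpy(int).reshape(shape),
            phase_centers_ms=np.full(n_p, np.nan),
            dummy_counts=np.zeros(0, int),
        )

    def meta_json(self) -> str:
        return json.dumps(
            {
                "n_phases": int(self.n_phases),
                "n_ti": int(self.n_ti),
                "offset_times_ms": list(self.offset_times_ms),
                "rr_ms": list(self.rr_ms),
                "phase_centers_ms": [float(v) for v in self.phase_centers_ms],
                "dummy_counts": [int(v) for v in self.dummy_counts],
            }
        )


def phase_centers(timing: CardiacTiming, acq_window_fraction: float) -> np.ndarray:
    """Centers of the cardiac-phase windows, ``(i + 0.5) * dt`` after the R-wave."""
    n = timing.n_phases(acq_window_fraction)
    return (np.arange(n) + 0.5) * timing.phase_duration_ms


def dummy_pulse_counts(params: SequenceParams, timing: CardiacTiming) -> np.ndarray:
    """Number of non-imaging FLASH pulses between the acquisition-window end
    and the next R-wave, per beat of the R-R series.

    The count is ``floor((RR - f*RR) / TR)`` with ``f`` the acquisition-window
    fraction; with a variable R-R series the count varies beat by beat.
    """
    rr = np.asarray(timing.rr_ms, float)
    gap = rr * (1.0 - params.acq_window_fraction)
    # 1e-9 guards against float round-off when the gap is an exact TR multiple
    return np.floor(gap / params.tr_ms + 1e-9).astype(int)


def plan_acquisition(
    params: SequenceParams, timing: CardiacTiming
) -> AcquisitionPlan:
    """Derive the full per-phase inversion-time table.

    For each cardiac phase (center ``c`` after the R-wave) and each inversion
    offset ``t_off``, the first sample falls at ``c - t_off`` after the
    inversion when ``c >= t_off``; phases preceding the inversion within the
    trigger beat are first sampled in the following beat (``RR + c - t_off``).
    Each subsequent recovery beat adds its own measured R-R interval, giving
    ``recovery_beats`` samples per offset.
    """
    centers = phase_centers(timing, params.acq_window_fraction)
    rr0 = timing.rr_of_beat(0)
    offsets = params.resolved_offsets(rr0)

    n_p = centers.size
    n_t = params.recovery_beats * len(offsets)
    ti = np.empty((n_p, n_t))
    off_idx = np.empty((n_p, n_t), int)
    beat_idx = np.empty((n_p, n_t), int)

    # Cumulative beat boundaries after the trigger beat, from the measured
    # R-R series (cycled); beat b adds sum(rr[0..b-1]).
    beat_start = np.concatenate(
        ([0.0], np.cumsum([timing.rr_of_beat(b) for b in range(params.recovery_beats)]))
    )

    col = 0
    for o, t_off in enumerate(offsets):
        base = centers - t_off
        wrapped = base < 0
        base = np.where(wrapped, base + rr0, base)
        for b in range(params.recovery_beats):
            ti[:, col] = base + beat_start[b]
            off_idx[:, col] = o
            beat_idx[:, col] = b
            col += 1

    if np.any(ti <= 0):
        raise InvalidParameterError(
            "offset configuration yields a non-positive inversion time"
        )

    order = np.argsort(ti, axis=1, kind="stable")
    rows = np.arange(n_p)[:, None]
    return AcquisitionPlan(
        ti_ms=ti[rows, order],
        offset_index=off_idx[rows, order],
        beat_index=beat_idx[rows, order],
        phase_centers_ms=centers,
        dummy_counts=dummy_pulse_counts(params, timing),
        offset_times_ms=offsets,
        rr_ms=timing.rr_ms,
    )


def with_offsets(params: SequenceParams, offsets: Sequence[float]) -> SequenceParams:
    """Copy of ``params`` with explicit inversion offsets."""
    return replace(params, offset_times_ms=tuple(float(t) for t in offsets))
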