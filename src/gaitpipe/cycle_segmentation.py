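"""Gait-cycle detection from the ankle-to-ankle distance signal.

During walking the Euclidean distance between the two ankles oscillates:
it is largest at full stride split and dips to a prominent local minimum
twice per stride, when the feet pass each other. A gait cycle is the span
of three consecutive such minima; to avoid edge effects at the start of a
recording, features are computed on the *second* cycle only.

Cycles tile the minima sequence without overlap, sharing endpoints: with
minima ``m1 < m2 < m3 < m4 < m5``, cycle 1 spans ``[m1, m3)`` and cycle 2
spans ``[m3, m5)`` (half-open frame windows, so consecutive cycles never
double-count a frame). Extraction therefore needs at least five detected
minima.

Failures are values, not exceptions: the cohort-level feasibility metric
counts them.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence, Union

import numpy as np

from .pose_model import PoseLandmark, PoseSequence


@dataclasses.dataclass(frozen=True)
class AnkleSignal:
    """Per-frame distance between the left and right ankle landmarks."""

    values: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("distances cannot be negative")
        object.__setattr__(self, "values", v)


@dataclasses.dataclass(frozen=True)
class CycleSegment:
    """The extracted second gait cycle of one recording."""

    minima_indices: tuple[int, ...]
    start_frame: int
    end_frame: int
    cycle_index: int = 2

    def __post_init__(self) -> None:
        m = self.minima_indices
        if any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("minima indices must be strictly increasing")
        if not self.start_frame < self.end_frame:
            raise ValueError("start_frame must precede end_frame")

    @property
    def n_frames(self) -> int:
        """Frame count of the half-open window [start_frame, end_frame)."""
        return self.end_frame - self.start_frame


@dataclasses.dataclass(frozen=True)
class SegmentationFailure:
    """Typed marker for a recording whose second cycle could not be found."""

    reason: str  # 'insufficient_minima' | 'irregular_cadence'
    n_minima: int


SegmentationResult = Union[CycleSegment, SegmentationFailure]


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the minima detector and the plausibility gate.

    smoothing_window
        Centered moving-average width in frames (odd); 1 disables smoothing.
    min_prominence_frac
        A minimum is kept only if its topographic prominence is at least
        this fraction of the smoothed signal's total range.
    max_gap_cv
        Reject the recording when the coefficient of variation of the
        inter-minima gaps exceeds this bound; walking produces near-regular
        minima while detection failures produce erratic ones.
    """

    smoothing_window: int = 5
    min_prominence_frac: float = 0.1
    max_gap_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if not 0 <= self.min_prominence_frac:
            raise ValueError("min_prominence_frac must be >= 0")


def ankle_distance(seq: PoseSequence) -> AnkleSignal:
    """Euclidean distance between LEFT_ANKLE and RIGHT_ANKLE, every frame."""
    xy = seq.xy()
    diff = xy[:, PoseLandmark.LEFT_ANKLE] - xy[:, PoseLandmark.RIGHT_ANKLE]
    return AnkleSignal(values=np.hypot(diff[:, 0], diff[:, 1]),
                       frame_rate_hz=seq.frame_rate_hz)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks near the edges."""
    if window == 1:
        return np.asarray(values, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones(len(values)), kernel, mode="same")
    return num / den


def _strict_minima_with_plateaus(x: np.ndarray) -> list[int]:
    """Interior strict local minima; plateaus resolve to their leftmost frame."""
    n = len(x)
    minima: list[int] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        # run [i, j] of equal values; interior minimum if both neighbors higher
        if j < n - 1 and x[i - 1] > x[i] and x[j + 1] > x[i]:
            minima.append(i)
        i = j + 1
    return minima


def _prominence_of_minimum(x: np.ndarray, idx: int) -> float:
    """Topographic prominence of the minimum at ``idx`` (on the inverted signal).

    On each side, walk outward until a value lower than ``x[idx]`` is found
    (or the signal ends); the side's base is the highest value encountered on
    that stretch. Prominence is ``min(left_base, right_base) - x[idx]``.
    """
    v = x[idx]
    left = x[:idx][::-1]
    right = x[idx + 1:]

    def base(side: np.ndarray) -> float:
        best = -np.inf
        for val in side:
            if val < v:
                break
            if val > best:
                best = val
        return best if np.isfinite(best) else np.inf

    lb, rb = base(left), base(right)
    if np.isinf(lb) and np.isinf(rb):
        return float(np.ptp(x))
    return float(min(lb, rb) - v)


def detect_minima(
    signal: AnkleSignal | np.ndarray,
    smoothing_window: int = 5,
    min_prominence_frac: float = 0.1,
) -> list[int]:
    """Prominent local minima of the (smoothed) ankle-distance signal.

    The signal is moving-average smoothed, strict interior minima are found
    (plateaus resolved to their leftmost frame), and a minimum is retained
    only if its prominence reaches ``min_prominence_frac`` of the smoothed
    signal's range. A constant signal yields an empty list.
    """
    values = signal.values if isinstance(signal, AnkleSignal) else np.asarray(signal, float)
    if len(values) < smoothing_window:
        raise ValueError("signal shorter than the smoothing window")
    sm = moving_average(values, smoothing_window)
    rng = float(sm.max() - sm.min())
    if rng == 0.0:
        return []
    threshold = min_prominence_frac * rng
    return [i for i in _strict_minima_with_plateaus(sm)
            if _prominence_of_minimum(sm, i) >= threshold]


def extract_second_cycle(
    seq: PoseSequence,
    params: SegmentationParams = SegmentationParams(),
) -> SegmentationResult:
    """Locate the second gait cycle, or report a typed failure.

    Requires at least five prominent minima (two full tiled cycles) and a
    plausibly regular cadence; uniform-noise "pose" from failed detections
    produces either too few prominent minima or erratically spaced ones and
    is rejected by the gap-regularity gate.
    """
    sig = ankle_distance(seq)
    minima = detect_minima(sig, params.smoothing_window, params.min_prominence_frac)
    if len(minima) < 5:
        return SegmentationFailure(reason="insufficient_minima", n_minima=len(minima))
    gaps = np.diff(minima)
    cv = float(gaps.std() / gaps.mean())
    if cv > params.max_gap_cv:
        return SegmentationFailure(reason="irregular_cadence", n_minima=len(minima))
    return CycleSegment(
        minima_indices=tuple(int(m) for m in minima),
        start_frame=int(minima[2]),
        end_frame=int(minima[4]),
    )


@dataclasses.dataclass(frozen=True)
class FeasibilityReport:
    n_success: int
    n_total: int

    @property
    def proportion(self) -> float:
        return self.n_success / self.n_total


def feasibility(
    results: Iterable[SegmentationResult] | Sequence[PoseSequence],
    params: SegmentationParams = SegmentationParams(),
) -> FeasibilityReport:
    """Proportion of recordings whose second cycle could be extracted.

    Accepts either precomputed segmentation results or raw pose sequences
    (which are segmented here).
    """
    items = list(results)
    if not items:
        raise ValueError("feasibility needs at least one record")
    if isinstance(items[0], PoseSequence):
        items = [extract_second_cycle(s, params) for s in items]
    n_success = sum(isinstance(r, CycleSegment) for r in items)
    return FeasibilityReport(n_success=n_success, n_total=len(items))
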