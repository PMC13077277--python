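"""Geometric gait features over the second cycle.

Per frame of the second gait cycle, 15 joint-pair distances (converted from
pixels to meters via an in-scene reference object of known length) and 12
interior joint angles (radians, convention-independent vector geometry) are
computed. Each of the 27 per-frame series is summarized by four moments —
mean, SD, skewness, kurtosis — over the cycle, and the cycle's frame count
is appended as a walking-speed surrogate, giving

    15 * 4 + 12 * 4 + 1 = 109

named features per recording.

The default pair and triplet sets are a documented reconstruction of the
commonly used torso/limb geometry (the upstream method's exact tables are
not public); both are configuration-replaceable. Angle triplets may refer
to the virtual midpoints ``mid_shoulder`` and ``mid_hip``, computed on the
fly and not counted as landmarks.

Moments use population (n-denominator) central moments: skewness is the
Fisher–Pearson g1 = m3 / m2^1.5 and kurtosis is excess g2 = m4 / m2^2 - 3.
A constant series has SD 0 and, by convention, skewness and kurtosis 0
(flagged), so downstream feature matrices stay dense.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cycle_segmentation import CycleSegment, SegmentationFailure, SegmentationResult
from .pose_model import (
    ConfigurationError,
    CoordinateSpace,
    GaitPipeError,
    PoseLandmark,
    PoseSequence,
    RecordingMeta,
)

MOMENT_STATS = ("mean", "sd", "skew", "kurt")

VIRTUAL_POINTS = ("mid_shoulder", "mid_hip")

_VALID_NAMES = {lm.name.lower() for lm in PoseLandmark} | set(VIRTUAL_POINTS)


class ExtractionError(GaitPipeError):
    """Raised when features are requested for a failed segmentation."""


DEFAULT_DISTANCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("left_shoulder", "right_shoulder"),
    ("left_hip", "right_hip"),
    ("left_shoulder", "left_hip"),
    ("right_shoulder", "right_hip"),
    ("left_elbow", "left_shoulder"),
    ("right_elbow", "right_shoulder"),
    ("left_wrist", "left_elbow"),
    ("right_wrist", "right_elbow"),
    ("left_knee", "left_hip"),
    ("right_knee", "right_hip"),
    ("left_ankle", "left_knee"),
    ("right_ankle", "right_knee"),
    ("left_ankle", "right_ankle"),
    ("left_heel", "left_foot_index"),
    ("right_heel", "right_foot_index"),
)

# (short name, (A, vertex, B)): the feature is the interior angle at the
# vertex between rays vertex->A and vertex->B.
DEFAULT_ANGLE_TRIPLETS: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("left_elbow", ("left_shoulder", "left_elbow", "left_wrist")),
    ("right_elbow", ("right_shoulder", "right_elbow", "right_wrist")),
    ("left_shoulder", ("left_hip", "left_shoulder", "left_elbow")),
    ("right_shoulder", ("right_hip", "right_shoulder", "right_elbow")),
    ("left_hip", ("left_shoulder", "left_hip", "left_knee")),
    ("right_hip", ("right_shoulder", "right_hip", "right_knee")),
    ("left_knee", ("left_hip", "left_knee", "left_ankle")),
    ("right_knee", ("right_hip", "right_knee", "right_ankle")),
    ("left_ankle", ("left_knee", "left_ankle", "left_foot_index")),
    ("right_ankle", ("right_knee", "right_ankle", "right_foot_index")),
    ("trunk", ("nose", "mid_shoulder", "mid_hip")),
    ("neck", ("left_ear", "nose", "mid_shoulder")),
)


@dataclasses.dataclass(frozen=True)
class DistancePairSet:
    """Exactly 15 unordered landmark pairs, each yielding one distance series."""

    pairs: tuple[tuple[str, str], ...] = DEFAULT_DISTANCE_PAIRS

    def __post_init__(self) -> None:
        if len(self.pairs) != 15:
            raise ConfigurationError(f"expected exactly 15 pairs, got {len(self.pairs)}")
        seen = set()
        for a, b in self.pairs:
            for name in (a, b):
                if name not in _VALID_NAMES:
                    raise ConfigurationError(f"unknown landmark name {name!r}")
            key = frozenset((a, b))
            if len(key) == 1 or key in seen:
                raise ConfigurationError(f"duplicate or degenerate pair ({a}, {b})")
            seen.add(key)

    @property
    def base_names(self) -> list[str]:
        return [f"d_{a}__{b}" for a, b in self.pairs]


@dataclasses.dataclass(frozen=True)
class AngleTripletSet:
    """Exactly 12 (A, vertex, B) triplets, each yielding one angle series."""

    triplets: tuple[tuple[str, tuple[str, str, str]], ...] = DEFAULT_ANGLE_TRIPLETS

    def __post_init__(self) -> None:
        if len(self.triplets) != 12:
            raise ConfigurationError(f"expected exactly 12 triplets, got {len(self.triplets)}")
        for name, (a, v, b) in self.triplets:
            for p in (a, v, b):
                if p not in _VALID_NAMES:
                    raise ConfigurationError(f"unknown landmark name {p!r} in triplet {name!r}")
            if a == v or b == v:
                raise ConfigurationError(f"triplet {name!r} has a ray endpoint equal to its vertex")

    @property
    def base_names(self) -> list[str]:
        return [f"ang_{name}" for name, _ in self.triplets]


@dataclasses.dataclass(frozen=True)
class ScaleFactor:
    meters_per_pixel: float

    def __post_init__(self) -> None:
        if not (self.meters_per_pixel > 0 and np.isfinite(self.meters_per_pixel)):
            raise ConfigurationError("meters_per_pixel must be strictly positive and finite")


def pixel_scale(reference_length_m: float, reference_length_px: float) -> ScaleFactor:
    """Scene scale from an in-video reference object of known length."""
    if not (reference_length_m > 0 and reference_length_px > 0):
        raise ConfigurationError("reference lengths must be strictly positive")
    return ScaleFactor(meters_per_pixel=reference_length_m / reference_length_px)


def feature_names(
    pairs: DistancePairSet = DistancePairSet(),
    triplets: AngleTripletSet = AngleTripletSet(),
) -> list[str]:
    """The frozen 109-name feature order: distances, angles, then the surrogate."""
    names = [f"{base}_{stat}" for base in pairs.base_names for stat in MOMENT_STATS]
    names += [f"{base}_{stat}" for base in triplets.base_names for stat in MOMENT_STATS]
    names.append("cycle_n_frames")
    return names


def _resolve(frame_xy: np.ndarray, name: str) -> np.ndarray:
    """Coordinates of a (possibly virtual) named point in one or many frames."""
    if name == "mid_shoulder":
        return 0.5 * (
            frame_xy[..., PoseLandmark.LEFT_SHOULDER, :]
            + frame_xy[..., PoseLandmark.RIGHT_SHOULDER, :]
        )
    if name == "mid_hip":
        return 0.5 * (
            frame_xy[..., PoseLandmark.LEFT_HIP, :] + frame_xy[..., PoseLandmark.RIGHT_HIP, :]
        )
    return frame_xy[..., PoseLandmark[name.upper()], :]


def frame_distances(
    frame_xy: np.ndarray,
    pairs: DistancePairSet,
    scale: ScaleFactor,
) -> np.ndarray:
    """The 15 pairwise distances, in meters. Accepts (33, 2) or (n, 33, 2)."""
    out = [
        np.linalg.norm(_resolve(frame_xy, a) - _resolve(frame_xy, b), axis=-1)
        for a, b in pairs.pairs
    ]
    return np.stack(out, axis=-1) * scale.meters_per_pixel


def frame_angles(
    frame_xy: np.ndarray,
    triplets: AngleTripletSet,
    degenerate_sentinel: float = 0.0,
) -> np.ndarray:
    """The 12 interior angles at each triplet's vertex, in [0, pi] radians.

    A zero-length ray makes the angle undefined; such entries get the
    configured sentinel (default 0.0) so feature matrices stay dense.
    """
    out = []
    for _, (a, v, b) in triplets.triplets:
        ra = _resolve(frame_xy, a) - _resolve(frame_xy, v)
        rb = _resolve(frame_xy, b) - _resolve(frame_xy, v)
        na = np.linalg.norm(ra, axis=-1)
        nb = np.linalg.norm(rb, axis=-1)
        denom = na * nb
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, (ra * rb).sum(axis=-1) / np.where(denom > 0, denom, 1.0), np.nan)
        ang = np.arccos(np.clip(cos, -1.0, 1.0))
        out.append(np.where(np.isnan(ang), degenerate_sentinel, ang))
    return np.stack(out, axis=-1)


def moment_summary(series: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd, skew, excess kurtosis) with population (n) denominators.

    A zero-variance series returns (mean, 0, 0, 0) rather than NaN.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("series must be nonempty")
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        return (mean, 0.0, 0.0, 0.0)
    # shape moments on standardized residuals: avoids underflow of m2**1.5
    # for near-constant series while staying exactly g1 and g2
    z = d / np.sqrt(m2)
    return (mean, float(np.sqrt(m2)), float(np.mean(z**3)), float(np.mean(z**4) - 3.0))


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """The 109 named features of one recording, in frozen order."""

    recording_id: str
    names: tuple[str, ...]
    values: np.ndarray
    degenerate_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if len(self.names) != 109:
            raise ValueError(f"expected 109 features, got {len(self.names)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def extract_features(
    seq: PoseSequence,
    segment: SegmentationResult,
    meta: RecordingMeta,
    pairs: DistancePairSet = DistancePairSet(),
    triplets: AngleTripletSet = AngleTripletSet(),
) -> FeatureVector:
    """The full 109-feature vector over the second cycle of one recording."""
    if isinstance(segment, SegmentationFailure):
        raise ExtractionError(
            f"{meta.recording_id}: cannot extract features from a failed "
            f"segmentation ({segment.reason}); filter feasibility failures first"
        )
    assert isinstance(segment, CycleSegment)
    if seq.coordinate_space is not CoordinateSpace.PIXEL:
        raise ConfigurationError("sequence must be in pixel space; apply to_pixel_space first")
    xy = seq.xy()[segment.start_frame:segment.end_frame]
    scale = pixel_scale(meta.reference_length_m, meta.reference_length_px)

    dists = frame_distances(xy, pairs, scale)      # (n, 15)
    angles = frame_angles(xy, triplets)            # (n, 12)

    values: list[float] = []
    flags: list[str] = []
    for series_block, bases in ((dists, pairs.base_names), (angles, triplets.base_names)):
        for j, base in enumerate(bases):
            mean, sd, skew, kurt = moment_summary(series_block[:, j])
            if sd == 0.0:
                flags.append(base)
            values.extend((mean, sd, skew, kurt))
    values.append(float(segment.n_frames))
    return FeatureVector(
        recording_id=meta.recording_id,
        names=tuple(feature_names(pairs, triplets)),
        values=np.asarray(values, dtype=float),
        degenerate_flags=tuple(flags),
    )
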