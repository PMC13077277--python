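"""Domain types and I/O for 2D pose-landmark sequences.

A recording is a time series of frames, each holding the 33 body landmarks
that markerless pose estimators such as MediaPipe emit (x, y, visibility).
Coordinates live either in pixel space (y increases downward, as in video
frames) or in normalized [0, 1] space; downstream geometry always works in
pixel space, so :func:`to_pixel_space` is the single conversion point.

Two on-disk schemas are supported:

* ``csv_long`` — header ``frame,landmark,x,y,visibility``, one row per
  landmark per frame, landmark as a 0–32 integer.
* ``jsonl_frames`` — one JSON object per line,
  ``{"frame": int, "landmarks": [[x, y, vis] * 33]}``.

Floats are serialized with ``repr`` so that write → read round-trips are
exact and two writes of the same sequence are byte-identical.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

N_LANDMARKS = 33


class GaitPipeError(Exception):
    """Base class for errors raised by this package."""


class SchemaError(GaitPipeError):
    """A file does not conform to the declared pose/metadata schema."""


class ConfigurationError(GaitPipeError):
    """An operation was invoked with inconsistent or missing configuration."""


class PoseLandmark(enum.IntEnum):
    """The 33 named body landmarks, 0-based.

    Downstream feature definitions refer to landmarks by these names only,
    never by raw index.
    """

    NOSE = 0
    LEFT_EYE_INNER = 1
    LEFT_EYE = 2
    LEFT_EYE_OUTER = 3
    RIGHT_EYE_INNER = 4
    RIGHT_EYE = 5
    RIGHT_EYE_OUTER = 6
    LEFT_EAR = 7
    RIGHT_EAR = 8
    MOUTH_LEFT = 9
    MOUTH_RIGHT = 10
    LEFT_SHOULDER = 11
    RIGHT_SHOULDER = 12
    LEFT_ELBOW = 13
    RIGHT_ELBOW = 14
    LEFT_WRIST = 15
    RIGHT_WRIST = 16
    LEFT_PINKY = 17
    RIGHT_PINKY = 18
    LEFT_INDEX = 19
    RIGHT_INDEX = 20
    LEFT_THUMB = 21
    RIGHT_THUMB = 22
    LEFT_HIP = 23
    RIGHT_HIP = 24
    LEFT_KNEE = 25
    RIGHT_KNEE = 26
    LEFT_ANKLE = 27
    RIGHT_ANKLE = 28
    LEFT_HEEL = 29
    RIGHT_HEEL = 30
    LEFT_FOOT_INDEX = 31
    RIGHT_FOOT_INDEX = 32


class CoordinateSpace(str, enum.Enum):
    PIXEL = "pixel"
    NORMALIZED = "normalized"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class AgeGroup(str, enum.Enum):
    UNDER65 = "under65"
    OVER65EQ = "over65eq"


class Site(str, enum.Enum):
    THAILAND = "thailand"
    INDIA = "india"


@dataclasses.dataclass(frozen=True)
class PoseSequence:
    """An ordered stack of pose frames for one recording.

    Parameters
    ----------
    landmarks
        Array of shape ``(n_frames, 33, 3)``: x, y, visibility per landmark.
    frame_rate_hz
        Sampling rate of the video, strictly positive.
    coordinate_space
        Whether x/y are pixels or normalized to [0, 1].
    image_width_px, image_height_px
        Frame dimensions; required to convert normalized coordinates.
    """

    landmarks: np.ndarray
    frame_rate_hz: float = 30.0
    coordinate_space: CoordinateSpace = CoordinateSpace.PIXEL
    image_width_px: int | None = None
    image_height_px: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.landmarks, dtype=float)
        if arr.ndim != 3 or arr.shape[1:] != (N_LANDMARKS, 3):
            raise SchemaError(
                f"landmarks must have shape (n_frames, {N_LANDMARKS}, 3); got {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise SchemaError("a pose sequence needs at least one frame")
        if not self.frame_rate_hz > 0:
            raise SchemaError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        vis = arr[:, :, 2]
        if np.any((vis < 0) | (vis > 1)):
            raise SchemaError("visibility values must lie in [0, 1]")
        if self.coordinate_space is CoordinateSpace.NORMALIZED:
            xy = arr[:, :, :2]
            if np.any((xy < 0) | (xy > 1)):
                # flagged, not silently clipped
                warnings.warn(
                    "normalized coordinates outside [0, 1]; leaving them unclipped",
                    stacklevel=2,
                )
        object.__setattr__(self, "landmarks", arr)

    @property
    def n_frames(self) -> int:
        return self.landmarks.shape[0]

    def xy(self) -> np.ndarray:
        """(n_frames, 33, 2) view of the coordinates."""
        return self.landmarks[:, :, :2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PoseSequence):
            return NotImplemented
        return (
            np.array_equal(self.landmarks, other.landmarks)
            and self.frame_rate_hz == other.frame_rate_hz
            and self.coordinate_space == other.coordinate_space
            and self.image_width_px == other.image_width_px
            and self.image_height_px == other.image_height_px
        )


@dataclasses.dataclass(frozen=True)
class RecordingMeta:
    """Per-recording metadata: labels, covariates and the scene scale."""

    recording_id: str
    sex: Sex
    age_years: float
    bmi: float
    site: Site
    reference_length_m: float
    reference_length_px: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "site", Site(self.site))
        if self.age_years < 0:
            raise SchemaError("age_years must be >= 0")
        if not self.bmi > 0:
            raise SchemaError("bmi must be > 0")
        if not (self.reference_length_m > 0 and self.reference_length_px > 0):
            raise SchemaError("reference lengths must be strictly positive")

    @property
    def age_group(self) -> AgeGroup:
        return AgeGroup.OVER65EQ if self.age_years >= 65 else AgeGroup.UNDER65


def to_pixel_space(seq: PoseSequence) -> PoseSequence:
    """Convert a sequence to pixel coordinates (idempotent).

    Normalized x is scaled by image width and y by image height; pixel-space
    input is returned unchanged.
    """
    if seq.coordinate_space is CoordinateSpace.PIXEL:
        return seq
    if seq.image_width_px is None or seq.image_height_px is None:
        raise ConfigurationError(
            "cannot convert normalized coordinates without image dimensions"
        )
    arr = seq.landmarks.copy()
    arr[:, :, 0] *= seq.image_width_px
    arr[:, :, 1] *= seq.image_height_px
    return PoseSequence(
        landmarks=arr,
        frame_rate_hz=seq.frame_rate_hz,
        coordinate_space=CoordinateSpace.PIXEL,
        image_width_px=seq.image_width_px,
        image_height_px=seq.image_height_px,
    )


def filter_low_visibility(seq: PoseSequence, min_mean_visibility: float) -> PoseSequence:
    """Optional frame filter: drop frames whose mean landmark visibility is low.

    Off by default throughout the pipeline — visibility is carried but not
    acted on unless explicitly requested. Raises if every frame would be
    dropped.
    """
    keep = seq.landmarks[:, :, 2].mean(axis=1) >= min_mean_visibility
    if not keep.any():
        raise ConfigurationError(
            f"no frame reaches mean visibility {min_mean_visibility}"
        )
    if keep.all():
        return seq
    return PoseSequence(
        landmarks=seq.landmarks[keep],
        frame_rate_hz=seq.frame_rate_hz,
        coordinate_space=seq.coordinate_space,
        image_width_px=seq.image_width_px,
        image_height_px=seq.image_height_px,
    )


_SCHEMAS = ("csv_long", "jsonl_frames")


def write_pose_sequence(seq: PoseSequence, path: str | Path, schema: str = "csv_long") -> None:
    """Serialize a sequence; identical input yields byte-identical files."""
    if schema not in _SCHEMAS:
        raise ConfigurationError(f"unknown schema {schema!r}; expected one of {_SCHEMAS}")
    path = Path(path)
    lines: list[str] = []
    if schema == "csv_long":
        lines.append("frame,landmark,x,y,visibility")
        for f in range(seq.n_frames):
            for lm in range(N_LANDMARKS):
                x, y, v = (float(c) for c in seq.landmarks[f, lm])
                lines.append(f"{f},{lm},{x!r},{y!r},{v!r}")
    else:
        for f in range(seq.n_frames):
            pts = [[float(c) for c in seq.landmarks[f, lm]] for lm in range(N_LANDMARKS)]
            lines.append(json.dumps({"frame": f, "landmarks": pts}))
    meta_line = json.dumps(
        {
            "frame_rate_hz": seq.frame_rate_hz,
            "coordinate_space": seq.coordinate_space.value,
            "image_width_px": seq.image_width_px,
            "image_height_px": seq.image_height_px,
        },
        sort_keys=True,
    )
    header = f"#gaitpipe {meta_line}\n"
    path.write_text(header + "\n".join(lines) + "\n")


def read_pose_sequence(path: str | Path, schema: str = "csv_long") -> PoseSequence:
    """Parse a pose file written in one of the supported schemas."""
    if schema not in _SCHEMAS:
        raise ConfigurationError(f"unknown schema {schema!r}; expected one of {_SCHEMAS}")
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    meta = {
        "frame_rate_hz": 30.0,
        "coordinate_space": "pixel",
        "image_width_px": None,
        "image_height_px": None,
    }
    if lines and lines[0].startswith("#gaitpipe "):
        meta.update(json.loads(lines[0][len("#gaitpipe "):]))
        lines = lines[1:]

    frames: dict[int, np.ndarray] = {}
    if schema == "csv_long":
        if not lines or lines[0].strip() != "frame,landmark,x,y,visibility":
            raise SchemaError(f"{path}: missing csv_long header")
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split(",")
            if len(parts) not in (4, 5):
                raise SchemaError(f"{path}: malformed row at line {ln}")
            try:
                f, lm = int(parts[0]), int(parts[1])
                x, y = float(parts[2]), float(parts[3])
                v = float(parts[4]) if len(parts) == 5 and parts[4] != "" else 1.0
            except ValueError as exc:
                raise SchemaError(f"{path}: malformed row at line {ln}: {exc}") from exc
            if not 0 <= lm < N_LANDMARKS:
                raise SchemaError(f"{path}: landmark index {lm} out of range at line {ln}")
            frame = frames.setdefault(f, np.full((N_LANDMARKS, 3), np.nan))
            frame[lm] = (x, y, v)
    else:
        for ln, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                f = int(obj["frame"])
                pts = obj["landmarks"]
            except (ValueError, KeyError, TypeError) as exc:
                raise SchemaError(f"{path}: malformed JSON at line {ln}: {exc}") from exc
            if len(pts) != N_LANDMARKS:
                raise SchemaError(
                    f"{path}: frame {f} has {len(pts)} landmarks, expected {N_LANDMARKS} (line {ln})"
                )
            arr = np.asarray(pts, dtype=float)
            if arr.shape[1] == 2:
                arr = np.column_stack([arr, np.ones(len(arr))])
            frames[f] = arr

    if not frames:
        raise SchemaError(f"{path}: no frames found")
    order = sorted(frames)
    stack = np.stack([frames[f] for f in order])
    if np.any(np.isnan(stack)):
        bad = [f for f in order if np.any(np.isnan(frames[f]))]
        raise SchemaError(f"{path}: frames {bad[:5]} do not carry all {N_LANDMARKS} landmarks")
    # missing visibility defaults to 1.0
    stack[:, :, 2] = np.where(np.isnan(stack[:, :, 2]), 1.0, stack[:, :, 2])
    return PoseSequence(
        landmarks=stack,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        coordinate_space=CoordinateSpace(meta["coordinate_space"]),
        image_width_px=meta["image_width_px"],
        image_height_px=meta["image_height_px"],
    )


METADATA_COLUMNS = [
    "recording_id",
    "sex",
    "age_years",
    "bmi",
    "site",
    "reference_length_m",
    "reference_length_px",
]


def write_metadata(records: list[RecordingMeta], path: str | Path) -> None:
    rows = [
        {
            "recording_id": m.recording_id,
            "sex": m.sex.value,
            "age_years": m.age_years,
            "bmi": m.bmi,
            "site": m.site.value,
            "reference_length_m": m.reference_length_m,
            "reference_length_px": m.reference_length_px,
        }
        for m in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_metadata(path: str | Path) -> list[RecordingMeta]:
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: metadata missing columns {sorted(missing)}")
    return [
        RecordingMeta(
            recording_id=str(r.recording_id),
            sex=Sex(r.sex),
            age_years=float(r.age_years),
            bmi=float(r.bmi),
            site=Site(r.site),
            reference_length_m=float(r.reference_length_m),
            reference_length_px=float(r.reference_length_px),
        )
        for r in df.itertuples()
    ]
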