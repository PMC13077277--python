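"""Synthetic sagittal-plane kinematic walker.

Generates labeled pose-landmark sequences with the statistical structure the
downstream analysis assumes: sex effects on morphology (shoulder/hip ratio,
stature, arm swing), age effects on gait timing (cadence, step length, phase
jitter), per-landmark estimation jitter, and occasional whole-recording
detection failures in which the "pose" is uniform noise.

The walker is deliberately stylized, not a biomechanical model: the pelvis
translates at constant mean speed, hip–knee–ankle chains follow sinusoidal
joint-angle trajectories in anti-phase between legs, arms swing in anti-phase
with the ipsilateral leg, the torso bobs at twice the stride frequency, and
face/hand landmarks ride as rigid offsets from the head and wrist anchors.
This is enough to give the ankle-to-ankle distance signal its real-data
shape — near-zero prominent minima twice per stride — with closed-form
timing, so every downstream stage can be checked against known ground truth.

All randomness flows through explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .pose_model import (
    AgeGroup,
    CoordinateSpace,
    PoseLandmark,
    PoseSequence,
    RecordingMeta,
    Sex,
    Site,
)

L = PoseLandmark

IMAGE_WIDTH_PX = 1280
IMAGE_HEIGHT_PX = 720

# Baseline (female, under-65) parameter medians. Lengths are fractions of
# stature; a ~1.6 m adult seen from 3–5 m at 720p spans roughly 400 px.
_BASE_STATURE_PX = 400.0
_REL = {
    "shoulder_width": 0.245,
    "hip_width": 0.191,
    "upper_arm": 0.172,
    "forearm": 0.157,
    "thigh": 0.245,
    "shank": 0.246,
    "foot": 0.076,
    "head_offset": 0.105,
    "trunk": 0.288,
}
_BASE_CADENCE_HZ = 0.92          # strides per second
_BASE_STEP_FRAC = 0.39           # step length as a fraction of stature
_BASE_ARM_SWING_RAD = 0.30
_BASE_KNEE_FLEX_RAD = 0.45
_BASE_TORSO_BOB_FRAC = 0.012
_BASE_PHASE_JITTER_SD = 0.010


@dataclasses.dataclass(frozen=True)
class SubjectParams:
    """Morphology and gait-timing parameters of one walker, pixel units."""

    stature_px: float
    shoulder_width_px: float
    hip_width_px: float
    upper_arm_px: float
    forearm_px: float
    thigh_px: float
    shank_px: float
    foot_px: float
    head_offset_px: float
    trunk_px: float
    cadence_hz: float
    step_length_px: float
    arm_swing_amp_rad: float
    knee_flex_amp_rad: float
    torso_bob_amp_px: float
    phase_jitter_sd: float

    def __post_init__(self) -> None:
        lengths = (
            self.stature_px, self.shoulder_width_px, self.hip_width_px,
            self.upper_arm_px, self.forearm_px, self.thigh_px, self.shank_px,
            self.foot_px, self.head_offset_px, self.trunk_px,
            self.cadence_hz, self.step_length_px,
        )
        if any(not v > 0 for v in lengths):
            raise ValueError("all lengths and cadence must be strictly positive")
        amps = (
            self.arm_swing_amp_rad, self.knee_flex_amp_rad,
            self.torso_bob_amp_px, self.phase_jitter_sd,
        )
        if any(v < 0 for v in amps):
            raise ValueError("amplitudes must be nonnegative")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dataclasses.fields(self)])


@dataclasses.dataclass(frozen=True)
class EffectConfig:
    """Group effects applied multiplicatively on top of the base draws.

    ``effect_scale`` raises every multiplier to that power (and scales the
    additive jitter shift linearly), so ``effect_scale = 0`` is an exact null
    world: group-conditional parameter distributions coincide.
    """

    male_stature_mult: float = 1.07
    male_shoulder_mult: float = 1.08
    male_hip_mult: float = 0.95
    male_arm_swing_mult: float = 1.15
    over65_cadence_mult: float = 0.93
    over65_step_length_mult: float = 0.94
    over65_phase_jitter_add: float = 0.02
    effect_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")


@dataclasses.dataclass(frozen=True)
class NoiseConfig:
    """Landmark-level and recording-level corruption of the clean walker."""

    jitter_sd_px: float = 2.0
    loose_clothing_mode: bool = False
    loose_clothing_factor: float = 3.0
    failure_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter_sd_px < 0:
            raise ValueError("jitter_sd_px must be >= 0")
        if not 0.0 <= self.failure_rate <= 1.0:
            raise ValueError("failure_rate must lie in [0, 1]")


# landmarks whose jitter is inflated under loose clothing
_LOWER_BODY = [L.LEFT_HIP, L.RIGHT_HIP, L.LEFT_KNEE, L.RIGHT_KNEE, L.LEFT_ANKLE, L.RIGHT_ANKLE]


def sample_subject(
    sex: Sex | str,
    age_group: AgeGroup | str,
    effects: EffectConfig = EffectConfig(),
    rng_seed: int = 0,
) -> SubjectParams:
    """Draw one subject's parameters from log-normal population distributions.

    Base draws are group-independent; group membership only multiplies the
    affected parameters, so seed-matched draws across groups are identical at
    ``effect_scale = 0``.
    """
    sex = Sex(sex)
    age_group = AgeGroup(age_group)
    rng = np.random.default_rng(rng_seed)
    s = effects.effect_scale

    def ln(base: float, sigma: float) -> float:
        return base * math.exp(sigma * rng.standard_normal())

    stature = ln(_BASE_STATURE_PX, 0.045)
    rel = {k: ln(v, 0.05) for k, v in _REL.items()}
    cadence = ln(_BASE_CADENCE_HZ, 0.06)
    step_frac = ln(_BASE_STEP_FRAC, 0.07)
    arm_swing = ln(_BASE_ARM_SWING_RAD, 0.18)
    knee_flex = ln(_BASE_KNEE_FLEX_RAD, 0.12)
    torso_bob_frac = ln(_BASE_TORSO_BOB_FRAC, 0.20)
    phase_jitter = _BASE_PHASE_JITTER_SD * math.exp(0.2 * rng.standard_normal())

    if sex is Sex.MALE:
        stature *= effects.male_stature_mult ** s
        rel["shoulder_width"] *= effects.male_shoulder_mult ** s
        rel["hip_width"] *= effects.male_hip_mult ** s
        arm_swing *= effects.male_arm_swing_mult ** s
    if age_group is AgeGroup.OVER65EQ:
        cadence *= effects.over65_cadence_mult ** s
        step_frac *= effects.over65_step_length_mult ** s
        phase_jitter += effects.over65_phase_jitter_add * s

    return SubjectParams(
        stature_px=stature,
        shoulder_width_px=rel["shoulder_width"] * stature,
        hip_width_px=rel["hip_width"] * stature,
        upper_arm_px=rel["upper_arm"] * stature,
        forearm_px=rel["forearm"] * stature,
        thigh_px=rel["thigh"] * stature,
        shank_px=rel["shank"] * stature,
        foot_px=rel["foot"] * stature,
        head_offset_px=rel["head_offset"] * stature,
        trunk_px=rel["trunk"] * stature,
        cadence_hz=cadence,
        step_length_px=step_frac * stature,
        arm_swing_amp_rad=arm_swing,
        knee_flex_amp_rad=knee_flex,
        torso_bob_amp_px=torso_bob_frac * stature,
        phase_jitter_sd=phase_jitter,
    )


# rigid offsets from the nose anchor, in stature units, (dx, dy), y down.
_FACE_OFFSETS = {
    L.LEFT_EYE_INNER: (0.010, -0.016),
    L.LEFT_EYE: (0.014, -0.017),
    L.LEFT_EYE_OUTER: (0.018, -0.016),
    L.RIGHT_EYE_INNER: (0.006, -0.017),
    L.RIGHT_EYE: (0.002, -0.018),
    L.RIGHT_EYE_OUTER: (-0.002, -0.017),
    L.LEFT_EAR: (-0.020, -0.008),
    L.RIGHT_EAR: (-0.026, -0.010),
    L.MOUTH_LEFT: (0.012, 0.012),
    L.MOUTH_RIGHT: (0.004, 0.013),
}

# rigid offsets from each wrist, in stature units.
_HAND_OFFSETS = {
    "pinky": (0.034, 0.012),
    "index": (0.040, 0.004),
    "thumb": (0.026, -0.006),
}


def generate_walk(
    subject: SubjectParams,
    n_strides: int = 4,
    frame_rate_hz: float = 30.0,
    noise: NoiseConfig = NoiseConfig(),
    rng_seed: int = 0,
) -> PoseSequence:
    """Render a side-view walk of ``n_strides`` strides as a pose sequence.

    The ankle-to-ankle distance of the clean walker is periodic with minima
    every ``1 / (2 * cadence)`` seconds (two steps per stride), which is the
    timing contract the gait-cycle segmenter relies on.
    """
    if n_strides < 3:
        raise ValueError("n_strides must be >= 3 so a second gait cycle exists")
    rng = np.random.default_rng(rng_seed)
    p = subject
    n_frames = int(round(n_strides / p.cadence_hz * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz

    phase = 2.0 * math.pi * p.cadence_hz * t
    if p.phase_jitter_sd > 0:
        # random-walk phase noise; SD per sqrt(second) = phase_jitter_sd rad
        steps = rng.normal(0.0, p.phase_jitter_sd / math.sqrt(frame_rate_hz), n_frames)
        phase = phase + np.cumsum(steps)

    speed = p.step_length_px * 2.0 * p.cadence_hz
    pelvis_x = 60.0 + speed * t
    leg_len = p.thigh_px + p.shank_px
    hip_y = (IMAGE_HEIGHT_PX - 60.0) - leg_len
    bob = p.torso_bob_amp_px * np.sin(2.0 * phase)
    hip_y_t = hip_y + bob

    theta_amp = math.asin(min(0.98, p.step_length_px / (2.0 * leg_len)))

    pts = np.zeros((n_frames, 33, 2))

    # knee flexion shared by both legs at twice the stride frequency (zero at
    # the foot crossings), which keeps the ankle-distance minima evenly
    # spaced at half-stride intervals — the timing contract downstream
    flex = p.knee_flex_amp_rad * 0.5 * (1.0 - np.cos(2.0 * phase))

    # Both leg chains hang from the pelvis center so the ankle x positions
    # coincide exactly twice per stride at half-stride intervals; the hip
    # landmarks themselves keep their width offsets (stylized projection of
    # pelvis width into the image plane).
    def leg(sign_phase: float, hip_lm_x: np.ndarray, knee_lm: L, ankle_lm: L,
            heel_lm: L, foot_lm: L, hip_lm: L) -> None:
        th = theta_amp * np.sin(phase + sign_phase)
        psi = th - flex
        kx = pelvis_x + p.thigh_px * np.sin(th)
        ky = hip_y_t + p.thigh_px * np.cos(th)
        ax = kx + p.shank_px * np.sin(psi)
        ay = ky + p.shank_px * np.cos(psi)
        pts[:, hip_lm, 0], pts[:, hip_lm, 1] = hip_lm_x, hip_y_t
        pts[:, knee_lm, 0], pts[:, knee_lm, 1] = kx, ky
        pts[:, ankle_lm, 0], pts[:, ankle_lm, 1] = ax, ay
        pts[:, heel_lm, 0] = ax - 0.30 * p.foot_px
        pts[:, heel_lm, 1] = ay + 0.15 * p.foot_px
        pts[:, foot_lm, 0] = ax + 0.70 * p.foot_px
        pts[:, foot_lm, 1] = ay + 0.20 * p.foot_px

    leg(0.0, pelvis_x - p.hip_width_px / 2, L.LEFT_KNEE, L.LEFT_ANKLE,
        L.LEFT_HEEL, L.LEFT_FOOT_INDEX, L.LEFT_HIP)
    leg(math.pi, pelvis_x + p.hip_width_px / 2, L.RIGHT_KNEE, L.RIGHT_ANKLE,
        L.RIGHT_HEEL, L.RIGHT_FOOT_INDEX, L.RIGHT_HIP)

    # rigid trunk anchored to the pelvis: shoulders bob with the hips
    ms_x = pelvis_x
    ms_y = hip_y_t - p.trunk_px
    pts[:, L.LEFT_SHOULDER, 0] = ms_x - p.shoulder_width_px / 2
    pts[:, L.LEFT_SHOULDER, 1] = ms_y
    pts[:, L.RIGHT_SHOULDER, 0] = ms_x + p.shoulder_width_px / 2
    pts[:, L.RIGHT_SHOULDER, 1] = ms_y

    def arm(sign_phase: float, sh_x: np.ndarray, elbow_lm: L, wrist_lm: L,
            hand: dict[str, L]) -> None:
        # anti-phase with the ipsilateral leg
        alpha = -p.arm_swing_amp_rad * np.sin(phase + sign_phase)
        ex = sh_x + p.upper_arm_px * np.sin(alpha)
        ey = ms_y + p.upper_arm_px * np.cos(alpha)
        beta = alpha + 0.35  # constant elbow flexion, forearm carried forward
        wx = ex + p.forearm_px * np.sin(beta)
        wy = ey + p.forearm_px * np.cos(beta)
        pts[:, elbow_lm, 0], pts[:, elbow_lm, 1] = ex, ey
        pts[:, wrist_lm, 0], pts[:, wrist_lm, 1] = wx, wy
        for part, lm in hand.items():
            dx, dy = _HAND_OFFSETS[part]
            pts[:, lm, 0] = wx + dx * p.stature_px
            pts[:, lm, 1] = wy + dy * p.stature_px

    arm(0.0, pts[:, L.LEFT_SHOULDER, 0], L.LEFT_ELBOW, L.LEFT_WRIST,
        {"pinky": L.LEFT_PINKY, "index": L.LEFT_INDEX, "thumb": L.LEFT_THUMB})
    arm(math.pi, pts[:, L.RIGHT_SHOULDER, 0], L.RIGHT_ELBOW, L.RIGHT_WRIST,
        {"pinky": L.RIGHT_PINKY, "index": L.RIGHT_INDEX, "thumb": L.RIGHT_THUMB})

    nose_x = ms_x + 0.020 * p.stature_px
    nose_y = ms_y - p.head_offset_px
    pts[:, L.NOSE, 0], pts[:, L.NOSE, 1] = nose_x, nose_y
    for lm, (dx, dy) in _FACE_OFFSETS.items():
        pts[:, lm, 0] = nose_x + dx * p.stature_px
        pts[:, lm, 1] = nose_y + dy * p.stature_px

    if noise.jitter_sd_px > 0:
        sd = np.full(33, noise.jitter_sd_px, dtype=float)
        if noise.loose_clothing_mode:
            sd[[int(lm) for lm in _LOWER_BODY]] *= noise.loose_clothing_factor
        pts = pts + rng.normal(0.0, 1.0, pts.shape) * sd[None, :, None]

    landmarks = np.concatenate([pts, np.ones((n_frames, 33, 1))], axis=2)
    return PoseSequence(
        landmarks=landmarks,
        frame_rate_hz=frame_rate_hz,
        coordinate_space=CoordinateSpace.PIXEL,
        image_width_px=IMAGE_WIDTH_PX,
        image_height_px=IMAGE_HEIGHT_PX,
    )


def generate_garbage(
    n_frames: int,
    frame_rate_hz: float = 30.0,
    rng_seed: int = 0,
) -> PoseSequence:
    """A failed detection: every landmark uniform over the image, every frame."""
    rng = np.random.default_rng(rng_seed)
    pts = np.empty((n_frames, 33, 3))
    pts[:, :, 0] = rng.uniform(0, IMAGE_WIDTH_PX, (n_frames, 33))
    pts[:, :, 1] = rng.uniform(0, IMAGE_HEIGHT_PX, (n_frames, 33))
    pts[:, :, 2] = 1.0
    return PoseSequence(
        landmarks=pts,
        frame_rate_hz=frame_rate_hz,
        coordinate_space=CoordinateSpace.PIXEL,
        image_width_px=IMAGE_WIDTH_PX,
        image_height_px=IMAGE_HEIGHT_PX,
    )


def largest_remainder_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer seat allocation of ``n`` across categories by largest remainder."""
    quotas = {k: n * f for k, f in fractions.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    leftover = n - sum(counts.values())
    order = sorted(quotas, key=lambda k: (quotas[k] - counts[k], k), reverse=True)
    for k in order[:leftover]:
        counts[k] += 1
    return counts


@dataclasses.dataclass(frozen=True)
class ClassBalance:
    """Cohort label fractions; defaults mirror the study demographics."""

    sex_female_frac: float = 94 / 145
    age_over65_frac: float = 55 / 145

    def __post_init__(self) -> None:
        for f in (self.sex_female_frac, self.age_over65_frac):
            if not 0.0 < f < 1.0:
                raise ValueError("class fractions must lie in (0, 1)")


def sample_cohort(
    n: int,
    class_balance: ClassBalance = ClassBalance(),
    effects: EffectConfig = EffectConfig(),
    noise: NoiseConfig = NoiseConfig(),
    site_thailand_frac: float = 51 / 145,
    rng_seed: int = 0,
    n_strides: int = 4,
    frame_rate_hz: float = 30.0,
) -> list[tuple[PoseSequence, RecordingMeta]]:
    """Simulate a labeled cohort of ``n`` recordings.

    Label counts follow the requested fractions exactly under
    largest-remainder rounding; a ``failure_rate`` fraction of recordings is
    independently replaced by garbage sequences that carry no flag — the
    segmenter must detect them. The reference object's pixel length depends
    on site (camera geometry), not on the subject, so metric distances retain
    morphological group differences.
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    rng = np.random.default_rng(rng_seed)

    sex_counts = largest_remainder_counts(
        n, {"female": class_balance.sex_female_frac, "male": 1 - class_balance.sex_female_frac}
    )
    age_counts = largest_remainder_counts(
        n, {"over65eq": class_balance.age_over65_frac, "under65": 1 - class_balance.age_over65_frac}
    )
    site_counts = largest_remainder_counts(
        n, {"thailand": site_thailand_frac, "india": 1 - site_thailand_frac}
    )
    sexes = [Sex.FEMALE] * sex_counts["female"] + [Sex.MALE] * sex_counts["male"]
    ages = [AgeGroup.OVER65EQ] * age_counts["over65eq"] + [AgeGroup.UNDER65] * age_counts["under65"]
    sites = [Site.THAILAND] * site_counts["thailand"] + [Site.INDIA] * site_counts["india"]
    sexes = [sexes[j] for j in rng.permutation(n)]
    ages = [ages[j] for j in rng.permutation(n)]
    sites = [sites[j] for j in rng.permutation(n)]

    out: list[tuple[PoseSequence, RecordingMeta]] = []
    for i in range(n):
        subj_seed, walk_seed, fail_seed = rng.integers(0, 2**31, size=3)
        subject = sample_subject(sexes[i], ages[i], effects, int(subj_seed))
        is_failure = rng.uniform() < noise.failure_rate
        if is_failure:
            n_frames = int(round(n_strides / subject.cadence_hz * frame_rate_hz))
            seq = generate_garbage(n_frames, frame_rate_hz, int(fail_seed))
        else:
            seq = generate_walk(subject, n_strides, frame_rate_hz, noise, int(walk_seed))

        age_years = (
            float(rng.uniform(65, 85))
            if ages[i] is AgeGroup.OVER65EQ
            else float(rng.uniform(35, 64.9))
        )
        # BMI log-normal, correlated with the subject's relative body width
        width_z = math.log(
            (subject.shoulder_width_px + subject.hip_width_px)
            / (subject.stature_px * (_REL["shoulder_width"] + _REL["hip_width"]))
        ) / 0.05
        bmi = 22.9 * math.exp(0.06 * width_z + 0.16 * rng.standard_normal())
        ref_px = (
            240.0 * math.exp(0.03 * rng.standard_normal())
            if sites[i] is Site.THAILAND
            else 300.0 * math.exp(0.03 * rng.standard_normal())
        )
        meta = RecordingMeta(
            recording_id=f"rec{i:04d}",
            sex=sexes[i],
            age_years=age_years,
            bmi=bmi,
            site=sites[i],
            reference_length_m=1.0,
            reference_length_px=ref_px,
        )
        out.append((seq, meta))
    return out
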