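"""Seeded synthetic rehabilitation-motion cohorts.

Emulates the statistical structure of a depth-camera physiotherapy study:
25 skeletal joints tracked per frame in four channel blocks (3-D position,
unit-quaternion orientation, 2-D colour-plane and 2-D depth-plane
projections), a per-frame clinical indicator series, static subject
covariates, a normalized 0–1 recovery label, a per-frame clinical recovery
scale, and multi-rater key-event annotations with controllable agreement.

Design of the signal structure
------------------------------
Each subject carries a latent movement-quality scalar ``q`` in [0, 1].

* The recovery label is ``y = clip(q + ε, 0, 1)`` — monotone in ``q`` at
  zero label noise.
* Baseline joint motion is a sum of smooth periodic limb oscillations whose
  amplitude, smoothness and postural stability improve mildly with ``q``
  (tremor and drift shrink as ``q`` grows), so frame-to-frame jerk
  decreases in ``q``.  Every baseline cue is blurred by trial-level
  execution variability (people differ in size, effort and steadiness from
  trial to trial), which caps how much of the label the out-of-window
  motion can reveal.
* The *label-discriminative* amplitude modulation — a windowed oscillatory
  burst on the lower-limb joints whose amplitude encodes ``q`` cleanly —
  is injected only inside the annotation windows, emulating the scored key
  movement events.  Attention models therefore have to look inside the
  clinically annotated windows to read the label accurately from the
  motion stream.
* The per-frame clinical recovery scale γ_t is a smoothed, noisy monotone
  transform of ``q`` with a mild within-session ramp; the first clinical
  indicator column tracks γ_t plus measurement noise, the remaining columns
  are autocorrelated nuisance series.
* Each of ``rater_count`` (odd) raters reproduces the true window indicator
  with per-frame flip probability ``1 − rater_agreement``; the consensus is
  the majority vote.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneratorConfig",
    "SubjectProfile",
    "AnnotationSet",
    "MultimodalSample",
    "GeneratorConfigError",
    "JOINT_NAMES",
    "LOWER_LIMB_JOINTS",
    "generate_cohort",
    "generate_sequence",
    "derive_recovery_score",
    "simulate_clinical_series",
    "simulate_raters",
    "sample_windows",
    "mean_squared_jerk",
]


class GeneratorConfigError(ValueError):
    """Raised for invalid generator configurations."""


#: Kinect-v2 joint order; the flattened feature layout follows this order.
JOINT_NAMES = [
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
]

#: joints receiving the label-relevant burst (lower-limb rehabilitation focus)
LOWER_LIMB_JOINTS = [
    "SpineBase", "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
]

# rest pose of a standing subject ~2.5 m from the camera (x lateral, y up,
# z depth); values in metres, deliberately schematic.
_BASE_POSE = {
    "SpineBase": (0.00, 1.00, 2.50), "SpineMid": (0.00, 1.25, 2.50),
    "Neck": (0.00, 1.50, 2.50), "Head": (0.00, 1.65, 2.50),
    "ShoulderLeft": (-0.20, 1.45, 2.50), "ElbowLeft": (-0.30, 1.20, 2.52),
    "WristLeft": (-0.33, 0.98, 2.54), "HandLeft": (-0.34, 0.90, 2.55),
    "ShoulderRight": (0.20, 1.45, 2.50), "ElbowRight": (0.30, 1.20, 2.52),
    "WristRight": (0.33, 0.98, 2.54), "HandRight": (0.34, 0.90, 2.55),
    "HipLeft": (-0.10, 0.95, 2.50), "KneeLeft": (-0.12, 0.55, 2.52),
    "AnkleLeft": (-0.13, 0.12, 2.54), "FootLeft": (-0.13, 0.05, 2.45),
    "HipRight": (0.10, 0.95, 2.50), "KneeRight": (0.12, 0.55, 2.52),
    "AnkleRight": (0.13, 0.12, 2.54), "FootRight": (0.13, 0.05, 2.45),
    "SpineShoulder": (0.00, 1.42, 2.50), "HandTipLeft": (-0.35, 0.84, 2.56),
    "ThumbLeft": (-0.31, 0.88, 2.55), "HandTipRight": (0.35, 0.84, 2.56),
    "ThumbRight": (0.31, 0.88, 2.55),
}

#: per-joint mobility scale (distal joints travel further)
_MOBILITY = {
    "SpineBase": 0.25, "SpineMid": 0.2, "Neck": 0.15, "Head": 0.2,
    "SpineShoulder": 0.2,
    "ShoulderLeft": 0.35, "ShoulderRight": 0.35,
    "ElbowLeft": 0.6, "ElbowRight": 0.6,
    "WristLeft": 0.85, "WristRight": 0.85,
    "HandLeft": 1.0, "HandRight": 1.0,
    "HandTipLeft": 1.0, "HandTipRight": 1.0,
    "ThumbLeft": 0.95, "ThumbRight": 0.95,
    "HipLeft": 0.3, "HipRight": 0.3,
    "KneeLeft": 0.7, "KneeRight": 0.7,
    "AnkleLeft": 0.9, "AnkleRight": 0.9,
    "FootLeft": 1.0, "FootRight": 1.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Defaults describe the desk-scale cohort used throughout the tests:
    60 subjects × 2 exercises, 100 frames per trial at 30 Hz, 25 joints,
    4 clinical indicator columns, ~10 % of frames carrying label-relevant
    signal in two brief key-event windows, and a three-rater annotation panel in
    the strong-agreement regime.
    """

    n_subjects: int = 60
    n_exercises: int = 2
    frames_per_trial: int = 100
    frame_rate: float = 30.0
    n_joints: int = 25
    clinical_dim: int = 4
    noise_sd: float = 0.01
    signal_window_fraction: float = 0.1
    rater_count: int = 3
    rater_agreement: float = 0.98
    n_distractor_events: int = 2
    label_noise_sd: float = 0.02
    gamma_subject_sd: float = 0.12
    gamma_noise_sd: float = 0.05
    clinical_noise_sd: float = 0.08
    include_image_channel: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_subjects", "n_exercises", "frames_per_trial",
                     "n_joints", "clinical_dim", "rater_count"):
            if getattr(self, name) < 1:
                raise GeneratorConfigError(f"{name} must be >= 1")
        if not (0.0 < self.signal_window_fraction < 1.0):
            raise GeneratorConfigError("signal_window_fraction must be in (0, 1)")
        if not (0.0 <= self.rater_agreement <= 1.0):
            raise GeneratorConfigError("rater_agreement must be in [0, 1]")
        if self.frame_rate <= 0:
            raise GeneratorConfigError("frame_rate must be positive")
        if self.frames_per_trial < 4:
            raise GeneratorConfigError("frames_per_trial too short for windows (need >= 4)")
        if self.n_joints != 25:
            raise GeneratorConfigError("the skeleton model defines 25 joints")
        if self.rater_count % 2 == 0:
            raise GeneratorConfigError("rater_count must be odd so majority voting is defined")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SubjectProfile:
    """One study participant with a latent movement quality ``q``."""

    subject_id: str
    age: float
    sex: str
    quality: float
    static_covariates: np.ndarray  # (normalized age, clinical severity, BMI z)

    def validate(self) -> None:
        if not (0.0 <= self.quality <= 1.0):
            raise ValueError("quality must be in [0, 1]")
        if self.static_covariates.shape[0] < 2:
            raise ValueError("static covariates must have length >= 2")


@dataclass
class AnnotationSet:
    """Therapist key-event windows and per-rater frame marks."""

    windows: list[tuple[int, int]]            # half-open [start, end)
    per_rater_marks: np.ndarray               # (R, T) in {0, 1}
    consensus_marks: np.ndarray               # (T,) in {0, 1}

    @property
    def n_frames(self) -> int:
        return int(self.consensus_marks.shape[0])

    @property
    def annotated_frames(self) -> np.ndarray:
        """Frame indices marked by the consensus."""
        return np.flatnonzero(self.consensus_marks)

    @property
    def coverage(self) -> float:
        """Fraction of frames annotated by the consensus (chance level of AAS)."""
        return float(self.consensus_marks.mean())

    def validate(self) -> None:
        T = self.n_frames
        prev_end = -1
        for s, e in self.windows:
            if not (0 <= s < e <= T):
                raise ValueError(f"window [{s}, {e}) outside [0, {T})")
            if s < prev_end:
                raise ValueError("windows must be sorted and non-overlapping")
            prev_end = e
        maj = (self.per_rater_marks.sum(axis=0) * 2 > self.per_rater_marks.shape[0])
        if not np.array_equal(maj.astype(np.int8), self.consensus_marks.astype(np.int8)):
            raise ValueError("consensus must be the majority vote of the raters")


@dataclass
class MultimodalSample:
    """One rehabilitation trial of a subject performing one exercise."""

    subject_id: str
    exercise_id: str
    position: np.ndarray       # (T, J, 3)
    orientation: np.ndarray    # (T, J, 4) unit quaternions (x, y, z, w)
    color2d: np.ndarray        # (T, J, 2)
    depth2d: np.ndarray        # (T, J, 2)
    clinical: np.ndarray       # (T, k)
    static_covariates: np.ndarray
    label: float               # recovery score in [0, 1]
    gamma: np.ndarray          # (T,) per-frame clinical recovery scale
    annotations: AnnotationSet
    image: np.ndarray | None = None   # (T, 8, 8) optional synthetic grid

    @property
    def n_frames(self) -> int:
        return int(self.position.shape[0])

    @property
    def n_joints(self) -> int:
        return int(self.position.shape[1])

    def validate(self) -> None:
        T, J = self.position.shape[:2]
        if self.orientation.shape != (T, J, 4):
            raise ValueError("orientation must be (T, J, 4)")
        norms = np.linalg.norm(self.orientation, axis=-1)
        if np.abs(norms - 1.0).max() > 1e-6:
            raise ValueError("quaternions must have unit norm within 1e-6")
        if not (0.0 <= self.label <= 1.0):
            raise ValueError("label must be in [0, 1]")
        if self.gamma.shape != (T,) or self.gamma.min() < 0 or self.gamma.max() > 1:
            raise ValueError("gamma must be (T,) with values in [0, 1]")
        if self.clinical.shape[0] != T:
            raise ValueError("clinical series must have one row per frame")
        self.annotations.validate()


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def derive_recovery_score(q: float, noise_sd: float, seed: int) -> float:
    """Recovery label y = clip(q + ε, 0, 1); monotone in q at zero noise."""
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must be in [0, 1]")
    eps = 0.0
    if noise_sd > 0:
        eps = float(np.random.default_rng(seed).normal(0.0, noise_sd))
    return float(np.clip(q + eps, 0.0, 1.0))


def sample_windows(T: int, fraction: float, rng: np.random.Generator,
                   n_windows: int = 2, n_extra: int = 0):
    """Place non-overlapping windows uniformly at random.

    The first ``n_windows`` intervals (sorted) are the annotated key-event
    windows, each spanning ``ceil(fraction * T / n_windows)`` frames; the
    ``n_extra`` others host incidental (distractor) events.  Which placed
    interval becomes annotated is chosen at random so position carries no
    information.  Returns ``(windows, extras)``; ``extras`` is empty when
    ``n_extra`` is 0.
    """
    total = n_windows + n_extra
    w = max(1, math.ceil(fraction * T / n_windows))
    if total * w > T:
        raise GeneratorConfigError("windows do not fit into the trial")
    starts = None
    for _ in range(10_000):
        cand = np.sort(rng.integers(0, T - w + 1, size=total))
        if all(cand[i + 1] >= cand[i] + w for i in range(total - 1)):
            starts = cand
            break
    if starts is None:  # deterministic fallback: evenly spaced
        step = T // total
        starts = np.array([i * step for i in range(total)])
    chosen = rng.permutation(total)[:n_windows]
    windows = sorted((int(starts[i]), int(starts[i] + w)) for i in chosen)
    extras = sorted((int(starts[i]), int(starts[i] + w))
                    for i in range(total) if i not in set(chosen))
    return windows, extras


def _smooth(x: np.ndarray, width: int = 9) -> np.ndarray:
    if x.shape[0] < width:
        return x
    k = np.hanning(width)
    k /= k.sum()
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, k, mode="valid")[: x.shape[0]]


def simulate_gamma(quality: float, T: int, config: GeneratorConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-frame clinical recovery scale: smoothed noisy monotone map of q.

    A subject-level offset (sd ``gamma_subject_sd``) makes γ an imperfect
    proxy of the label across subjects; a mild within-session ramp gives γ
    temporal structure.
    """
    base = quality
    if config.gamma_subject_sd > 0:
        base = base + rng.normal(0.0, config.gamma_subject_sd)
    ramp = 0.1 * (np.arange(T) / max(T - 1, 1) - 0.5)
    noise = np.zeros(T)
    if config.gamma_noise_sd > 0:
        noise = _smooth(rng.normal(0.0, config.gamma_noise_sd, size=T))
    return np.clip(base + ramp + noise, 0.0, 1.0)


def simulate_clinical_series(gamma: np.ndarray, k: int, config: GeneratorConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """T×k clinical indicator matrix.

    Column 0 tracks γ_t plus measurement noise; columns 1..k−1 are
    standardized AR(1) nuisance series carrying no label information.
    """
    if k < 1:
        raise ValueError("clinical_dim must be >= 1")
    T = gamma.shape[0]
    C = np.zeros((T, k))
    C[:, 0] = gamma
    if config.clinical_noise_sd > 0:
        C[:, 0] = C[:, 0] + rng.normal(0.0, config.clinical_noise_sd, size=T)
    for j in range(1, k):
        x = np.zeros(T)
        innov = rng.normal(0.0, 0.3, size=T)
        for t in range(T):
            x[t] = (0.9 * x[t - 1] if t else 0.0) + innov[t]
        sd = x.std()
        C[:, j] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return C


def simulate_raters(windows: list[tuple[int, int]], T: int, rater_count: int,
                    agreement: float, seed: int) -> AnnotationSet:
    """Multi-rater annotation panel with per-frame flip probability 1−agreement."""
    if rater_count % 2 == 0:
        raise GeneratorConfigError("rater_count must be odd so majority voting is defined")
    rng = np.random.default_rng(seed)
    truth = np.zeros(T, dtype=np.int8)
    for s, e in windows:
        truth[s:e] = 1
    flip_p = 1.0 - agreement
    flips = rng.random((rater_count, T)) < flip_p
    marks = np.where(flips, 1 - truth[None, :], truth[None, :]).astype(np.int8)
    consensus = (marks.sum(axis=0) * 2 > rater_count).astype(np.int8)
    return AnnotationSet(windows=list(windows), per_rater_marks=marks,
                         consensus_marks=consensus)


# ---------------------------------------------------------------------------
# motion synthesis
# ---------------------------------------------------------------------------

def _project(position: np.ndarray, focal: float, offset: float,
             noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Pinhole-style projection of 3-D positions onto a 2-D plane."""
    x, y, z = position[..., 0], position[..., 1], position[..., 2]
    u = focal * x / z + offset
    v = focal * y / z + offset
    out = np.stack([u, v], axis=-1)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out


def _add_event(position: np.ndarray, t: np.ndarray, s: int, e: int,
               amp: float, freq: float, joints: np.ndarray,
               mob: np.ndarray, dim_amp: np.ndarray,
               depth: float = 0.0) -> None:
    """Inject one movement event into frames [s, e).

    ``amp`` scales the oscillatory marker; ``depth`` adds a signed smooth
    postural excursion (extension depth) under the same envelope.
    """
    tau = (np.arange(s, e) - s) / max(e - s, 1)
    envelope = np.sin(np.pi * tau)
    carrier = np.sin(2.0 * np.pi * freq * (t[s:e] - t[s]) + 0.3)
    wave = amp * envelope * carrier + depth * envelope
    position[s:e][:, joints, :] += (wave[:, None, None]
                                    * dim_amp[None, None, :]
                                    * mob[joints][None, :, None])


def generate_sequence(profile: SubjectProfile, exercise_id: str,
                      config: GeneratorConfig, seed: int,
                      windows: list[tuple[int, int]],
                      distractors: list[tuple[int, int]] = ()):
    """Synthesize one trial's skeleton block, γ series and optional image grid.

    Returns ``(position, orientation, color2d, depth2d, gamma, image)``.
    The label-relevant amplitude modulation is injected only inside the
    annotated ``windows``; ``distractors`` receive same-signature events
    with label-irrelevant amplitude, and outside all events the motion
    statistics depend on ``q`` solely through weak smoothness/stability
    cues blurred by execution variability.
    """
    T, J = config.frames_per_trial, config.n_joints
    if T < 4:
        raise GeneratorConfigError("frames_per_trial too short for windows (need >= 4)")
    q = profile.quality
    rng = np.random.default_rng(seed)
    t = np.arange(T) / config.frame_rate

    # per-exercise base frequency and phase layout
    ex_hash = sum(ord(ch) for ch in str(exercise_id)) % 7
    f0 = 0.4 + 0.08 * ex_hash
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(J, 3))
    dim_amp = np.array([1.0, 0.8, 0.35])  # lateral/vertical motion dominates depth

    base = np.array([_BASE_POSE[n] for n in JOINT_NAMES])       # (J, 3)
    mob = np.array([_MOBILITY[n] for n in JOINT_NAMES])         # (J,)

    # trial-level execution variability plus a slowly varying within-trial
    # effort curve: effort/steadiness fluctuate between and during trials,
    # blurring every baseline cue to the subject's quality
    exec_scale = 1.0 + 0.1 * rng.standard_normal()
    steadiness = 1.0 + 0.5 * abs(rng.standard_normal())
    effort = 1.0 + 0.25 * _smooth(rng.standard_normal(T), width=21)

    # smooth periodic limb motion; amplitude only mildly quality-dependent
    amp = 0.06 * mob * (0.95 + 0.05 * q) * exec_scale           # (J,)
    osc = np.sin(2.0 * np.pi * f0 * t[:, None, None] + phases[None, :, :])
    second = 0.4 * np.sin(2.0 * np.pi * 2.0 * f0 * t[:, None, None]
                          + 1.7 * phases[None, :, :])
    position = base[None, :, :] + (effort[:, None, None]
                                   * amp[None, :, None] * dim_amp[None, None, :]
                                   * (osc + second))

    # instability: tremor and slow postural drift shrink with quality but are
    # dominated by the trial-level steadiness factor
    tremor_scale = 0.02 * (1.0 - 0.5 * q) * steadiness
    tremor = tremor_scale * rng.standard_normal((T, J, 3))
    # postural drift with random per-joint loadings: a slow wander whose
    # spatial pattern differs between trials, so no fixed cross-joint
    # regression can subtract it
    loadings = rng.standard_normal((1, J, 3))
    drift = (0.05 * (1.0 - 0.5 * q) * steadiness * loadings
             * np.cumsum(rng.standard_normal((T, 1, 1)), axis=0)
             / np.sqrt(T))
    position = position + tremor + drift

    # movement events on the lower limbs.  Each event couples
    #   (i) an oscillatory *marker* whose amplitude is quality-independent —
    #       it says "a movement event happens here" without leaking the
    #       label into any global energy statistic, and
    #  (ii) a smooth postural *excursion* (extension depth) that is signed
    #       around the neutral execution: δ ∝ (q − ½) for the scored
    #       (annotated) events and δ ∝ (u − ½), u label-irrelevant, for the
    #       incidental events.
    # Averaged over the whole trial the excursions of scored and incidental
    # events mix and the slow postural drift swamps what remains, so the
    # label is read cleanly only by pooling the annotated frames — the
    # structure that rewards temporally aligned attention.
    burst_joints = np.array([JOINT_NAMES.index(n) for n in LOWER_LIMB_JOINTS])
    marker_amp = 0.28 * (1.0 + 0.1 * rng.standard_normal())
    for s, e in windows:
        _add_event(position, t, s, e, marker_amp, 1.3 * f0,
                   burst_joints, mob, dim_amp, depth=0.3 * (q - 0.5))
    for s, e in distractors:
        u = float(np.clip(rng.normal(0.5, 0.2), 0.0, 1.0))
        _add_event(position, t, s, e, marker_amp, 1.3 * f0,
                   burst_joints, mob, dim_amp, depth=0.3 * (u - 0.5))

    if config.noise_sd > 0:
        position = position + rng.normal(0.0, config.noise_sd, size=position.shape)

    # joint orientations: small rotations about fixed per-joint axes
    axes = rng.standard_normal((J, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    theta = (0.3 * (0.95 + 0.05 * q) * exec_scale
             * np.sin(2.0 * np.pi * f0 * t[:, None] + phases[None, :, 0])
             + 0.03 * (1.0 - 0.5 * q) * steadiness
             * rng.standard_normal((T, J)))
    half = theta / 2.0
    orientation = np.empty((T, J, 4))
    orientation[..., :3] = np.sin(half)[..., None] * axes[None, :, :]
    orientation[..., 3] = np.cos(half)
    orientation /= np.linalg.norm(orientation, axis=-1, keepdims=True)

    color2d = _project(position, focal=1.2, offset=0.5,
                       noise_sd=config.noise_sd, rng=rng)
    depth2d = _project(position, focal=1.0, offset=0.4,
                       noise_sd=config.noise_sd, rng=rng)

    gamma = simulate_gamma(q, T, config, rng)

    image = None
    if config.include_image_channel:
        image = _render_density_grid(color2d)

    return position, orientation, color2d, depth2d, gamma, image


def _render_density_grid(color2d: np.ndarray, size: int = 8) -> np.ndarray:
    """Synthetic stand-in for a neuroimaging channel: per-frame 8×8 grid of
    joint density in the colour plane.  A schematic surrogate only — it does
    not emulate real imaging."""
    T = color2d.shape[0]
    lo = color2d.reshape(-1, 2).min(axis=0)
    hi = color2d.reshape(-1, 2).max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    grids = np.zeros((T, size, size), dtype=np.float32)
    for f in range(T):
        ij = np.clip(((color2d[f] - lo) / span * (size - 1)).astype(int), 0, size - 1)
        np.add.at(grids[f], (ij[:, 1], ij[:, 0]), 1.0)
    return grids / color2d.shape[1]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig):
    """Generate the full cohort.

    Returns ``(samples, profiles)`` with ``n_subjects × n_exercises``
    validated :class:`MultimodalSample` objects.  Bit-identical for
    identical (config, seed).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.spawn(config.n_subjects)

    samples: list[MultimodalSample] = []
    profiles: list[SubjectProfile] = []
    for i in range(config.n_subjects):
        s_rng = np.random.default_rng(subject_seeds[i])
        age = float(s_rng.uniform(20.0, 60.0))
        sex = "F" if s_rng.random() < 0.4 else "M"
        q = float(s_rng.uniform(0.05, 0.95))
        severity = float(np.clip(1.0 - q + s_rng.normal(0.0, 0.2), 0.0, 1.0))
        covariates = np.array([(age - 20.0) / 40.0, severity,
                               float(s_rng.normal(0.0, 1.0))])
        profile = SubjectProfile(subject_id=f"S{i:03d}", age=age, sex=sex,
                                 quality=q, static_covariates=covariates)
        profile.validate()
        profiles.append(profile)

        for e in range(config.n_exercises):
            trial_seed = int(s_rng.integers(0, 2**31 - 1))
            t_rng = np.random.default_rng(trial_seed)
            windows, distractors = sample_windows(
                config.frames_per_trial, config.signal_window_fraction,
                t_rng, n_windows=2, n_extra=config.n_distractor_events)
            label = derive_recovery_score(q, config.label_noise_sd,
                                          int(t_rng.integers(0, 2**31 - 1)))
            pos, quat, col, dep, gamma, image = generate_sequence(
                profile, f"E{e:02d}", config,
                int(t_rng.integers(0, 2**31 - 1)), windows, distractors)
            clinical = simulate_clinical_series(
                gamma, config.clinical_dim, config, t_rng)
            ann = simulate_raters(windows, config.frames_per_trial,
                                  config.rater_count, config.rater_agreement,
                                  int(t_rng.integers(0, 2**31 - 1)))
            sample = MultimodalSample(
                subject_id=profile.subject_id, exercise_id=f"E{e:02d}",
                position=pos, orientation=quat, color2d=col, depth2d=dep,
                clinical=clinical, static_covariates=covariates.copy(),
                label=label, gamma=gamma, annotations=ann, image=image)
            sample.validate()
            samples.append(sample)
    return samples, profiles


# ---------------------------------------------------------------------------
# kinematic helpers used by tests and explainability
# ---------------------------------------------------------------------------

def mean_squared_jerk(position: np.ndarray, frame_rate: float = 30.0) -> float:
    """Mean squared third-order finite difference of joint positions.

    A standard movement-smoothness statistic: lower values mean smoother,
    more controlled motion.
    """
    jerk = np.diff(position, n=3, axis=0) * frame_rate**3
    return float(np.mean(jerk**2))
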