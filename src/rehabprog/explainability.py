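"""Interpretability artifacts: temporal×joint attention heatmaps,
permutation-sampling Shapley attributions on kinematic summary features,
and correct/incorrect case reports aligned to therapist annotations.

The Shapley engine is implemented natively (exact enumeration for small
feature sets, permutation sampling otherwise) so the efficiency and
symmetry axioms are directly testable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohortsim import JOINT_NAMES, MultimodalSample, mean_squared_jerk

__all__ = [
    "HeatmapMatrix",
    "AttributionReport",
    "CaseReport",
    "KINEMATIC_FEATURES",
    "kinematic_features",
    "temporal_joint_heatmap",
    "shapley_values",
    "shapley_attribution",
    "fit_feature_surrogate",
    "case_report",
]


@dataclass
class HeatmapMatrix:
    """J×T nonnegative attention intensity (rows joints, columns frames)."""

    values: np.ndarray
    joint_labels: list[str]
    frame_indices: np.ndarray
    uniform_gates: bool = False

    def validate(self) -> None:
        if self.values.min() < 0 or not np.isfinite(self.values).all():
            raise ValueError("heatmap entries must be finite and nonnegative")


@dataclass
class AttributionReport:
    """Shapley estimates per named feature with Monte-Carlo errors."""

    feature_names: list[str]
    phi: np.ndarray
    std_errors: np.ndarray
    baseline_prediction: float
    full_prediction: float

    @property
    def efficiency_residual(self) -> float:
        return float(self.phi.sum()
                     - (self.full_prediction - self.baseline_prediction))


@dataclass
class CaseReport:
    """Prediction provenance of a single trial for clinician review."""

    sample_id: str
    yhat: float
    y: float
    correct: bool
    aas: float | None
    top_attended_frames: list[int]
    annotated_windows: list[tuple[int, int]]
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id, "yhat": self.yhat, "y": self.y,
            "correct": self.correct, "aas": self.aas,
            "top_attended_frames": list(map(int, self.top_attended_frames)),
            "annotated_windows": [list(w) for w in self.annotated_windows],
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# kinematic summary features
# ---------------------------------------------------------------------------

KINEMATIC_FEATURES = [
    "hip_stability",          # variance of hip-joint positions (lower = stabler)
    "knee_amplitude",         # range of the knee flexion-extension angle
    "motion_smoothness",      # mean squared jerk of all joints
    "center_of_mass_stability",  # variance of the skeleton centroid
    "coordination_variance",  # cross-joint variance of limb angles
]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle at vertex b of the polyline a-b-c, per frame."""
    v1 = a - b
    v2 = c - b
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1) + 1e-12)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def kinematic_features(sample: MultimodalSample,
                       frame_rate: float = 30.0) -> np.ndarray:
    """The five named kinematic summary statistics of a trial.

    Explicit realizations of the feature names used for attribution:
    hip positional variance, knee-angle range, mean squared jerk, centroid
    variance and cross-joint angle variance.
    """
    pos = sample.position
    j = {n: JOINT_NAMES.index(n) for n in JOINT_NAMES}
    hips = pos[:, [j["HipLeft"], j["HipRight"]], :]
    hip_stability = float(hips.reshape(hips.shape[0], -1).var(axis=0).mean())

    knee_l = _angle(pos[:, j["HipLeft"]], pos[:, j["KneeLeft"]],
                    pos[:, j["AnkleLeft"]])
    knee_r = _angle(pos[:, j["HipRight"]], pos[:, j["KneeRight"]],
                    pos[:, j["AnkleRight"]])
    knee_amplitude = float(np.mean([np.ptp(knee_l), np.ptp(knee_r)]))

    smoothness = mean_squared_jerk(pos, frame_rate)

    centroid = pos.mean(axis=1)
    com_stability = float(centroid.var(axis=0).mean())

    elbow_l = _angle(pos[:, j["ShoulderLeft"]], pos[:, j["ElbowLeft"]],
                     pos[:, j["WristLeft"]])
    elbow_r = _angle(pos[:, j["ShoulderRight"]], pos[:, j["ElbowRight"]],
                     pos[:, j["WristRight"]])
    angles = np.stack([knee_l, knee_r, elbow_l, elbow_r], axis=1)
    coordination = float(angles.var(axis=1).mean())

    return np.array([hip_stability, knee_amplitude, smoothness,
                     com_stability, coordination])


# ---------------------------------------------------------------------------
# heatmap
# ---------------------------------------------------------------------------

def temporal_joint_heatmap(alpha: np.ndarray, gates: np.ndarray | None,
                           uniform_fallback: bool = True) -> HeatmapMatrix:
    """Heatmap entry (j, t) = gate_j(t) × α_t.

    Gates are normalized per frame so each column sums to α_t and the total
    mass equals Σ_t α_t = 1.  A model trained without gates yields uniform
    joint rows, flagged on the result.
    """
    alpha = np.asarray(alpha, dtype=float)
    T = alpha.shape[0]
    uniform = False
    if gates is None:
        if not uniform_fallback:
            raise ValueError("model has no joint gates")
        gates = np.full((T, len(JOINT_NAMES)), 1.0 / len(JOINT_NAMES))
        uniform = True
    gates = np.asarray(gates, dtype=float)
    gates = gates / gates.sum(axis=1, keepdims=True)
    if np.allclose(gates, gates[0, 0]):
        uniform = True
    values = (gates * alpha[:, None]).T          # (J, T)
    hm = HeatmapMatrix(values=values, joint_labels=list(JOINT_NAMES),
                       frame_indices=np.arange(T), uniform_gates=uniform)
    hm.validate()
    return hm


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

def _coalition_value(f, x: np.ndarray, baseline: np.ndarray,
                     subset: tuple[int, ...]) -> float:
    z = baseline.copy()
    z[list(subset)] = x[list(subset)]
    return float(f(z))


def shapley_values(f, x: np.ndarray, baseline: np.ndarray,
                   n_permutations: int | None = None,
                   seed: int | None = None):
    """Shapley values of ``f`` at ``x`` against ``baseline``.

    Exact enumeration when ``n_permutations`` is None (p ≤ 10 features
    recommended); otherwise permutation sampling with Monte-Carlo standard
    errors.  Efficiency (Σφ = f(x) − f(baseline)) holds exactly in
    enumeration mode and in expectation when sampling.
    """
    x = np.asarray(x, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    p = x.size
    if n_permutations is None:
        phi = np.zeros(p)
        for subset_size in range(p):
            w = (math.factorial(subset_size)
                 * math.factorial(p - subset_size - 1) / math.factorial(p))
            for subset in itertools.combinations(range(p), subset_size):
                v_s = _coalition_value(f, x, baseline, subset)
                present = set(subset)
                for i in range(p):
                    if i in present:
                        continue
                    v_si = _coalition_value(f, x, baseline,
                                            tuple(sorted(present | {i})))
                    phi[i] += w * (v_si - v_s)
        return phi, np.zeros(p)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    contribs = np.zeros((n_permutations, p))
    for r in range(n_permutations):
        order = rng.permutation(p)
        prev = float(f(baseline))
        z = baseline.copy()
        for i in order:
            z[i] = x[i]
            cur = float(f(z))
            contribs[r, i] = cur - prev
            prev = cur
    phi = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations) \
        if n_permutations > 1 else np.full(p, np.nan)
    return phi, se


def fit_feature_surrogate(feature_matrix: np.ndarray,
                          predictions: np.ndarray, ridge: float = 1e-3):
    """Ridge-regression surrogate mapping standardized kinematic features to
    model predictions; returns ``(predict_fn, feature_stats)``.

    Used to attribute a sequence model's output to named summary features:
    the Shapley game is played on the surrogate, whose fidelity (R² against
    the model) should be checked before interpreting the attributions.
    """
    F = np.asarray(feature_matrix, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    mean, sd = F.mean(axis=0), F.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Z = (F - mean) / sd
    Zb = np.column_stack([Z, np.ones(len(Z))])
    A = Zb.T @ Zb + ridge * np.eye(Zb.shape[1])
    coef = np.linalg.solve(A, Zb.T @ yhat)

    def predict_fn(features: np.ndarray) -> float:
        z = (np.asarray(features, dtype=float) - mean) / sd
        return float(z @ coef[:-1] + coef[-1])

    return predict_fn, {"mean": mean, "sd": sd, "coef": coef}


def shapley_attribution(predict_fn, features: np.ndarray,
                        baseline: np.ndarray,
                        feature_names: list[str] | None = None,
                        n_permutations: int | None = None,
                        seed: int | None = None) -> AttributionReport:
    """Attribution report for one sample's feature vector."""
    names = feature_names or list(KINEMATIC_FEATURES)
    phi, se = shapley_values(predict_fn, features, baseline,
                             n_permutations=n_permutations, seed=seed)
    return AttributionReport(
        feature_names=names, phi=phi, std_errors=se,
        baseline_prediction=float(predict_fn(baseline)),
        full_prediction=float(predict_fn(np.asarray(features, dtype=float))))


# ---------------------------------------------------------------------------
# case reports
# ---------------------------------------------------------------------------

def case_report(sample: MultimodalSample, yhat: float, alpha: np.ndarray,
                threshold: float = 0.5) -> CaseReport:
    """Assemble a per-trial report: prediction, correctness at the
    threshold, sample-level AAS and the attended vs annotated windows."""
    from .eval_metrics import _sample_aas

    alpha = np.asarray(alpha, dtype=float)
    correct = (yhat >= threshold) == (sample.label >= threshold)
    annotated = sample.annotations.annotated_frames
    flags: list[str] = []
    aas: float | None
    if annotated.size == 0:
        warnings.warn("sample has no annotations; AAS omitted",
                      RuntimeWarning, stacklevel=2)
        aas = None
        flags.append("missing_annotations")
        top = np.argsort(-alpha, kind="stable")[:5]
    else:
        aas = _sample_aas(alpha, annotated)
        top = np.argsort(-alpha, kind="stable")[: annotated.size]
    return CaseReport(
        sample_id=f"{sample.subject_id}/{sample.exercise_id}",
        yhat=float(yhat), y=float(sample.label), correct=bool(correct),
        aas=aas, top_attended_frames=sorted(int(i) for i in top),
        annotated_windows=list(sample.annotations.windows), flags=flags)
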