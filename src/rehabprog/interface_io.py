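"""Dataset containers, checkpoints and run configuration.

Cohorts are stored as one HDF5 container (per-sample groups holding the
four skeleton channel blocks, the clinical series, γ, and the annotation
arrays) next to a ``manifest.json`` carrying schema version, counts, the
generator configuration with its hash, and per-sample SHA-256 checksums.
Model checkpoints are a single HDF5 container of named parameter groups
with a JSON sidecar of configuration and ablation switches.

The flattened per-frame feature layout is fixed: joints-major, and within
each joint the channel blocks in the order position (3), orientation (4),
color2d (2), depth2d (2) — 11 values per joint, 275 per frame for the
25-joint skeleton.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import h5py
import numpy as np

from . import cohortsim
from .cohortsim import AnnotationSet, GeneratorConfig, MultimodalSample, SubjectProfile
from .rrl_core import EncoderConfig, PolicyParams
from .xpt_core import LossConfig, ModelConfig, PrognosisModel, init_model

__all__ = [
    "SCHEMA_VERSION",
    "CohortIOError",
    "ConfigError",
    "RunConfig",
    "flatten_frames",
    "cohort_arrays",
    "config_hash",
    "save_cohort",
    "load_cohort",
    "save_checkpoint",
    "load_checkpoint",
    "load_run_config",
]

SCHEMA_VERSION = 1


class CohortIOError(RuntimeError):
    """Container/manifest integrity failure."""


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


# ---------------------------------------------------------------------------
# feature layout
# ---------------------------------------------------------------------------

def flatten_frames(sample: MultimodalSample) -> np.ndarray:
    """(T, 11·J) flattened frames in the fixed joints-major layout."""
    per_joint = np.concatenate(
        [sample.position, sample.orientation, sample.color2d, sample.depth2d],
        axis=-1)                               # (T, J, 11)
    T = per_joint.shape[0]
    return per_joint.reshape(T, -1)


def cohort_arrays(samples: list[MultimodalSample]) -> dict:
    """Stack a cohort into batch arrays for training/evaluation."""
    return {
        "X": np.stack([flatten_frames(s) for s in samples]),
        "C": np.stack([s.clinical for s in samples]),
        "S": np.stack([s.static_covariates for s in samples]),
        "y": np.array([s.label for s in samples]),
        "gamma": np.stack([s.gamma for s in samples]),
        "subjects": np.array([s.subject_id for s in samples]),
        "annotations": [s.annotations for s in samples],
        "samples": samples,
    }


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

_SAMPLE_ARRAYS = ("position", "orientation", "color2d", "depth2d",
                  "clinical", "gamma")


def _sample_checksum(sample: MultimodalSample) -> str:
    h = hashlib.sha256()
    for name in _SAMPLE_ARRAYS:
        h.update(np.ascontiguousarray(getattr(sample, name)).tobytes())
    h.update(np.ascontiguousarray(sample.static_covariates).tobytes())
    h.update(np.float64(sample.label).tobytes())
    h.update(np.ascontiguousarray(sample.annotations.per_rater_marks).tobytes())
    return h.hexdigest()


def save_cohort(samples: list[MultimodalSample], profiles: list[SubjectProfile],
                path, config: GeneratorConfig | None = None) -> pathlib.Path:
    """Write the cohort container and manifest under ``path`` (a directory).

    Returns the container path.  ``load_cohort(save_cohort(x))`` reproduces
    the numeric content bit-exactly.
    """
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    container = path / "cohort.h5"
    checksums = {}
    with h5py.File(container, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for i, s in enumerate(samples):
            s.validate()
            g = f.create_group(f"sample_{i:04d}")
            sk = g.create_group("skeleton")
            sk.create_dataset("position", data=s.position)
            sk.create_dataset("orientation", data=s.orientation)
            sk.create_dataset("color2d", data=s.color2d)
            sk.create_dataset("depth2d", data=s.depth2d)
            g.create_dataset("clinical", data=s.clinical)
            g.create_dataset("gamma", data=s.gamma)
            g.create_dataset("static_covariates", data=s.static_covariates)
            ann = g.create_group("annotations")
            ann.create_dataset("windows", data=np.array(s.annotations.windows,
                                                        dtype=np.int64)
                               .reshape(-1, 2))
            ann.create_dataset("per_rater_marks",
                               data=s.annotations.per_rater_marks)
            ann.create_dataset("consensus_marks",
                               data=s.annotations.consensus_marks)
            if s.image is not None:
                g.create_dataset("image", data=s.image)
            g.attrs["label"] = s.label
            g.attrs["subject_id"] = s.subject_id
            g.attrs["exercise_id"] = s.exercise_id
            checksums[f"sample_{i:04d}"] = _sample_checksum(s)
        pg = f.create_group("profiles")
        for p in profiles:
            gp = pg.create_group(p.subject_id)
            gp.attrs["age"] = p.age
            gp.attrs["sex"] = p.sex
            gp.attrs["quality"] = p.quality
            gp.create_dataset("static_covariates", data=p.static_covariates)

    first = samples[0]
    cfg_dict = config.to_dict() if config is not None else {}
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n_samples": len(samples),
        "n_subjects": len(profiles),
        "T": first.n_frames,
        "J": first.n_joints,
        "k": int(first.clinical.shape[1]),
        "frame_rate": cfg_dict.get("frame_rate"),
        "seed": cfg_dict.get("seed"),
        "generator_config": cfg_dict,
        "config_hash": config_hash(cfg_dict),
        "checksums": checksums,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return container


def load_cohort(path):
    """Load and verify a cohort; returns ``(samples, profiles, manifest)``.

    Raises :class:`CohortIOError` on schema-version mismatch, checksum
    mismatch or invariant violations (e.g. non-unit quaternions).
    """
    path = pathlib.Path(path)
    container = path / "cohort.h5" if path.is_dir() else path
    manifest_path = container.parent / "manifest.json"
    if not manifest_path.exists():
        raise CohortIOError(f"missing manifest next to {container}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise CohortIOError(
            f"schema version {manifest.get('schema_version')} != {SCHEMA_VERSION}")
    samples: list[MultimodalSample] = []
    profiles: list[SubjectProfile] = []
    with h5py.File(container, "r") as f:
        if int(f.attrs["schema_version"]) != SCHEMA_VERSION:
            raise CohortIOError("container schema version mismatch")
        names = sorted(n for n in f if n.startswith("sample_"))
        if len(names) != manifest["n_samples"]:
            raise CohortIOError("manifest n_samples does not match container")
        for name in names:
            g = f[name]
            ann = AnnotationSet(
                windows=[tuple(map(int, w)) for w in g["annotations/windows"][()]],
                per_rater_marks=g["annotations/per_rater_marks"][()],
                consensus_marks=g["annotations/consensus_marks"][()])
            s = MultimodalSample(
                subject_id=str(g.attrs["subject_id"]),
                exercise_id=str(g.attrs["exercise_id"]),
                position=g["skeleton/position"][()],
                orientation=g["skeleton/orientation"][()],
                color2d=g["skeleton/color2d"][()],
                depth2d=g["skeleton/depth2d"][()],
                clinical=g["clinical"][()], gamma=g["gamma"][()],
                static_covariates=g["static_covariates"][()],
                label=float(g.attrs["label"]), annotations=ann,
                image=g["image"][()] if "image" in g else None)
            expected = manifest["checksums"].get(name)
            if expected is not None and _sample_checksum(s) != expected:
                raise CohortIOError(f"checksum mismatch for {name}")
            try:
                s.validate()
            except ValueError as exc:
                raise CohortIOError(f"invalid sample {name}: {exc}") from exc
            samples.append(s)
        if "profiles" in f:
            for sid in sorted(f["profiles"]):
                gp = f["profiles"][sid]
                profiles.append(SubjectProfile(
                    subject_id=sid, age=float(gp.attrs["age"]),
                    sex=str(gp.attrs["sex"]),
                    quality=float(gp.attrs["quality"]),
                    static_covariates=gp["static_covariates"][()]))
    return samples, profiles, manifest


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: PrognosisModel, path) -> pathlib.Path:
    """Write parameters + policy + normalisation stats to one HDF5 file with
    a JSON sidecar of the configuration."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        pg = f.create_group("params")
        for k, v in model.params.items():
            pg.create_dataset(k, data=v.data)
        pol = f.create_group("policy")
        for k in ("W_mean", "b_mean", "log_std", "W_v", "W_aux"):
            pol.create_dataset(k, data=getattr(model.policy, k))
        pol.attrs["b_v"] = model.policy.b_v
        pol.attrs["b_aux"] = model.policy.b_aux
        for k in ("zeta", "alpha", "beta"):
            pol.attrs[k] = getattr(model.policy, k)
        ng = f.create_group("norm")
        for k, v in model.norm.items():
            ng.create_dataset(k, data=v)
    cfg = dataclasses.asdict(model.config)
    sidecar = {"schema_version": SCHEMA_VERSION, "model_config": cfg,
               "config_hash": config_hash(cfg)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path) -> PrognosisModel:
    path = pathlib.Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(sidecar["model_config"])
    enc_dict = dict(cfg_dict.pop("encoder"))
    enc_dict["channels"] = tuple(enc_dict["channels"])
    enc = EncoderConfig(**enc_dict)
    loss = LossConfig(**cfg_dict.pop("loss"))
    cfg = ModelConfig(encoder=enc, loss=loss, **cfg_dict)
    model = init_model(cfg, seed=0)
    with h5py.File(path, "r") as f:
        for k in f["params"]:
            model.params[k].data = f["params"][k][()]
        pol = f["policy"]
        for k in ("W_mean", "b_mean", "log_std", "W_v", "W_aux"):
            setattr(model.policy, k, pol[k][()])
        model.policy.b_v = float(pol.attrs["b_v"])
        model.policy.b_aux = float(pol.attrs["b_aux"])
        model.policy.zeta = float(pol.attrs["zeta"])
        model.policy.alpha = float(pol.attrs["alpha"])
        model.policy.beta = float(pol.attrs["beta"])
        model.norm = {k: f["norm"][k][()] for k in f["norm"]}
    return model


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {"generator", "model", "rrl", "train", "eval"}

_SECTION_KEYS = {
    "generator": {f.name for f in dataclasses.fields(GeneratorConfig)},
    "model": {"d_model", "n_heads", "n_layers", "d_ff", "d_attn",
              "embedding_dim", "channels", "kernel", "lam", "mode",
              "use_drl", "use_cnn", "use_transformer", "use_dual_loss",
              "use_gates", "use_context_encoding", "dtype"},
    "rrl": {"zeta", "alpha", "beta", "lr_actor", "lr_critic", "lr_aux"},
    "train": {"lr", "weight_decay", "batch_size", "patience", "max_epochs",
              "rl_updates_per_epoch", "seed"},
    "eval": {"threshold", "bins", "k_folds", "val_fraction"},
}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML file."""

    generator: GeneratorConfig
    model: ModelConfig
    rrl: dict
    train: "object"
    eval: dict
    raw: dict

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def load_run_config(path) -> RunConfig:
    """Parse and strictly validate a YAML run configuration.

    Unknown sections or keys raise :class:`ConfigError`.
    """
    import yaml

    from .training import TrainConfig

    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping")
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    for sec, keys in _SECTION_KEYS.items():
        extra = set(raw.get(sec, {}) or {}) - keys
        if extra:
            raise ConfigError(f"unknown keys in [{sec}]: {sorted(extra)}")

    gen_kwargs = dict(raw.get("generator", {}) or {})
    try:
        gen = GeneratorConfig(**gen_kwargs)
        gen.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid generator config: {exc}") from exc

    m = dict(raw.get("model", {}) or {})
    enc = EncoderConfig(
        n_features=gen.n_joints * 11,
        kernel=int(m.pop("kernel", 5)),
        channels=tuple(m.pop("channels", (24, 24))),
        embedding_dim=int(m.pop("embedding_dim", 32)))
    loss = LossConfig(mode=m.pop("mode", "bce"), lam=float(m.pop("lam", 0.1)))
    try:
        model_cfg = ModelConfig(
            n_joints=gen.n_joints, clinical_dim=gen.clinical_dim,
            static_dim=3, encoder=enc, loss=loss, **m)
        model_cfg.loss.validate()
        _ = model_cfg.d_k
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid model config: {exc}") from exc

    try:
        train_cfg = TrainConfig(**(raw.get("train", {}) or {}))
        train_cfg.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid train config: {exc}") from exc

    eval_cfg = {"threshold": 0.5, "bins": 10, "k_folds": 5,
                "val_fraction": 0.1}
    eval_cfg.update(raw.get("eval", {}) or {})
    rrl_cfg = {"zeta": 0.95, "alpha": 0.6, "beta": 0.4}
    rrl_cfg.update(raw.get("rrl", {}) or {})
    if abs(rrl_cfg["alpha"] + rrl_cfg["beta"] - 1.0) > 1e-9:
        raise ConfigError("reward weights must satisfy α + β = 1")

    return RunConfig(generator=gen, model=model_cfg, rrl=rrl_cfg,
                     train=train_cfg, eval=eval_cfg, raw=raw)
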