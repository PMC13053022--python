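"""Synthetic search-scene generation, phantom padding, and scene (de)serialization.

A scene is the latent state of the search problem: a set of labelled objects at
3-D gaze-direction locations on the viewing sphere, a feature matrix ``A``
(objects x features) whose rows are the objects' true feature values, and a
single designated target. Scenes are padded to a fixed maximum object count
with *phantom* objects -- zero-feature placeholder rows parked at the screen
center -- so that ensembles of unequal size share one tensor layout.

Feature values of real objects are marginally standard normal, matching the
searcher's N(0, 1) prior over true features. An optional similarity knob mixes
distractor rows toward the target row, making discrimination harder while
keeping the marginal feature scale at unity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

SCHEMA_VERSION = 1

#: Default maximum object count per scene (1 target + up to 112 distractors).
MAX_OBJECTS_DEFAULT = 113

_UNIT_TOL = 1e-9


class SceneError(ValueError):
    """Raised when a scene violates its structural invariants."""


@dataclass(frozen=True)
class Scene:
    """Latent state of one visual-search episode.

    Parameters
    ----------
    object_ids
        String label per object row.
    locations
        ``(N_o, 3)`` unit gaze-direction vectors. Phantom rows sit at the
        canonical screen-center direction.
    features
        ``(N_o, N_f)`` true feature matrix ``A``. Phantom rows are zero.
    target_index
        Row index of the unique target (never a phantom).
    phantom_mask
        Boolean per row; True marks padding rows.
    deadline_s
        Search deadline in seconds (drives the default fixation budget).
    """

    object_ids: list[str]
    locations: np.ndarray
    features: np.ndarray
    target_index: int
    phantom_mask: np.ndarray
    deadline_s: float = 8.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "locations", np.asarray(self.locations, dtype=float))
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        object.__setattr__(self, "phantom_mask", np.asarray(self.phantom_mask, dtype=bool))
        self._validate()

    def _validate(self) -> None:
        n = len(self.object_ids)
        if self.locations.shape != (n, 3):
            raise SceneError(f"locations must be ({n}, 3), got {self.locations.shape}")
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise SceneError(f"features must have {n} rows, got {self.features.shape}")
        if self.phantom_mask.shape != (n,):
            raise SceneError("phantom_mask length mismatch")
        if not (0 <= self.target_index < n):
            raise SceneError(f"target_index {self.target_index} out of range [0, {n})")
        if self.phantom_mask[self.target_index]:
            raise SceneError("the target must not be a phantom object")
        if self.deadline_s <= 0:
            raise SceneError("deadline_s must be positive")
        norms = np.linalg.norm(self.locations[~self.phantom_mask], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise SceneError("non-phantom locations must be unit vectors")
        if np.any(self.features[self.phantom_mask] != 0.0):
            raise SceneError("phantom feature rows must be exactly zero")

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_real(self) -> int:
        return int((~self.phantom_mask).sum())

    @property
    def target_features(self) -> np.ndarray:
        """True feature vector of the target (``f_target``)."""
        return self.features[self.target_index]


@dataclass(frozen=True)
class SceneGeneratorConfig:
    """Parameters of the synthetic scene ensemble.

    ``n_objects_min``/``n_objects_max`` count real objects including the
    target; the defaults (56..113) emulate rooms with 55-112 distractors plus
    one target. ``distractor_similarity`` in [0, 1) mixes distractor feature
    rows toward the target row. Locations are uniform in a spherical cap of
    half-angle ``cap_half_angle_deg`` around ``cap_axis`` (the head-fixed
    field of regard; also the canonical screen-center direction).
    """

    n_objects_min: int = 56
    n_objects_max: int = 113
    n_features: int = 6
    distractor_similarity: float = 0.0
    cap_half_angle_deg: float = 60.0
    cap_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    deadline_s: float = 8.0
    max_objects: int = MAX_OBJECTS_DEFAULT
    allow_single_object: bool = False

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise SceneError("n_features must be >= 1")
        if self.n_objects_min > self.n_objects_max:
            raise SceneError("empty n_objects range")
        min_allowed = 1 if self.allow_single_object else 2
        if self.n_objects_min < min_allowed:
            raise SceneError(
                f"n_objects must be >= {min_allowed} (search is undefined with a lone "
                "target unless allow_single_object is set)"
            )
        if self.n_objects_max > self.max_objects:
            raise SceneError("n_objects_max exceeds max_objects")
        if not 0.0 <= self.distractor_similarity < 1.0:
            raise SceneError("distractor_similarity must lie in [0, 1)")
        if not 0.0 < self.cap_half_angle_deg <= 180.0:
            raise SceneError("cap_half_angle_deg must lie in (0, 180]")

    @property
    def axis(self) -> np.ndarray:
        a = np.asarray(self.cap_axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise SceneError("cap_axis must be nonzero")
        return a / n


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to ``axis``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def sample_cap_directions(
    n: int, axis: np.ndarray, half_angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` unit vectors uniformly (by solid angle) in a spherical cap."""
    cos_min = math.cos(math.radians(half_angle_deg))
    cos_t = rng.uniform(cos_min, 1.0, size=n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    u, v = _orthonormal_frame(axis)
    dirs = (
        cos_t[:, None] * axis[None, :]
        + (sin_t * np.cos(phi))[:, None] * u[None, :]
        + (sin_t * np.sin(phi))[:, None] * v[None, :]
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def generate_scene(config: SceneGeneratorConfig, rng_seed: int) -> Scene:
    """Draw one scene from the synthetic ensemble.

    Real-object features are i.i.d. standard normal. With similarity s > 0
    each distractor row d is replaced by (s*t + (1-s)*d) / sqrt(s^2 + (1-s)^2),
    where t is the target row: the mixture pulls distractors toward the target
    while the divisor restores a unit marginal standard deviation, so the
    searcher's standard-normal prior stays calibrated at every s.
    """
    rng = np.random.default_rng(rng_seed)
    n = int(rng.integers(config.n_objects_min, config.n_objects_max + 1))
    features = rng.standard_normal((n, config.n_features))
    target_index = int(rng.integers(n))
    s = config.distractor_similarity
    if s > 0.0:
        t = features[target_index].copy()
        scale = math.sqrt(s**2 + (1.0 - s) ** 2)
        mixed = (s * t[None, :] + (1.0 - s) * features) / scale
        mixed[target_index] = t
        features = mixed
    locations = sample_cap_directions(n, config.axis, config.cap_half_angle_deg, rng)
    return Scene(
        object_ids=[f"obj_{i:03d}" for i in range(n)],
        locations=locations,
        features=features,
        target_index=target_index,
        phantom_mask=np.zeros(n, dtype=bool),
        deadline_s=config.deadline_s,
    )


def generate_ensemble(
    config: SceneGeneratorConfig, n_scenes: int, rng_seed: int, pad_to: int | None = None
) -> list[Scene]:
    """Generate ``n_scenes`` scenes with per-scene child seeds of ``rng_seed``."""
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_scenes)
    scenes = [generate_scene(config, int(s)) for s in seeds]
    if pad_to is not None:
        scenes = [pad_with_phantoms(sc, pad_to, axis=config.axis) for sc in scenes]
    return scenes


def pad_with_phantoms(
    scene: Scene, max_objects: int, axis: np.ndarray | None = None
) -> Scene:
    """Pad ``scene`` to exactly ``max_objects`` rows with phantom objects.

    Phantoms carry zero features and zero posterior mass and sit at the
    canonical screen-center direction (the cap axis). Idempotent; never
    alters existing rows or the target index.
    """
    if scene.n_objects > max_objects:
        raise SceneError(
            f"scene has {scene.n_objects} objects, more than max_objects={max_objects}"
        )
    k = max_objects - scene.n_objects
    if k == 0:
        return scene
    center = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    center = center / np.linalg.norm(center)
    return Scene(
        object_ids=scene.object_ids + [f"phantom_{i:03d}" for i in range(k)],
        locations=np.vstack([scene.locations, np.tile(center, (k, 1))]),
        features=np.vstack([scene.features, np.zeros((k, scene.n_features))]),
        target_index=scene.target_index,
        phantom_mask=np.concatenate([scene.phantom_mask, np.ones(k, dtype=bool)]),
        deadline_s=scene.deadline_s,
    )


def restrict_features(scene: Scene, k: int) -> Scene:
    """Scene with only the first ``k`` feature columns (e.g. leading PCs)."""
    if not 1 <= k <= scene.n_features:
        raise SceneError(f"k={k} outside [1, {scene.n_features}]")
    return replace(scene, features=scene.features[:, :k].copy())


def project_to_screen(locations: np.ndarray, axis: np.ndarray | None = None) -> np.ndarray:
    """Deterministic equirectangular projection of gaze directions to [-1, 1]^2.

    Azimuth about ``axis`` maps to x in [-1, 1] (half-turn = 1) and elevation
    to y. The axis itself (screen center, where phantoms sit) maps to (0, 0).
    """
    axis = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    u, v = _orthonormal_frame(axis)
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    z = locs @ axis
    x = locs @ u
    y = locs @ v
    azim = np.arctan2(x, z) / math.pi
    elev = np.arcsin(np.clip(y, -1.0, 1.0)) / (math.pi / 2.0)
    return np.stack([azim, elev], axis=-1)


def scene_to_dict(scene: Scene) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "object_ids": list(scene.object_ids),
        "locations": scene.locations.tolist(),
        "features": scene.features.tolist(),
        "target_index": int(scene.target_index),
        "phantom_mask": [bool(b) for b in scene.phantom_mask],
        "deadline_s": float(scene.deadline_s),
    }


def scene_from_dict(payload: dict) -> Scene:
    required = {
        "schema_version",
        "object_ids",
        "locations",
        "features",
        "target_index",
        "phantom_mask",
        "deadline_s",
    }
    missing = required - payload.keys()
    if missing:
        raise SceneError(f"scene record missing fields: {sorted(missing)}")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise SceneError(f"unsupported schema_version {payload['schema_version']}")
    if "target_indices" in payload or not isinstance(payload["target_index"], int):
        raise SceneError("exactly one integer target_index is required")
    return Scene(
        object_ids=list(payload["object_ids"]),
        locations=np.asarray(payload["locations"], dtype=float),
        features=np.asarray(payload["features"], dtype=float),
        target_index=payload["target_index"],
        phantom_mask=np.asarray(payload["phantom_mask"], dtype=bool),
        deadline_s=float(payload["deadline_s"]),
    )


def write_scene(scene: Scene, path) -> None:
    with open(path, "w") as fh:
        json.dump(scene_to_dict(scene), fh)


def read_scene(path) -> Scene:
    with open(path) as fh:
        payload = json.load(fh)
    return scene_from_dict(payload)
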