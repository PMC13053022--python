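"""Object representations for search: D2 shape histograms, L*a*b* color
vectors, pooled CNN embeddings, and PCA reduction.

Two routes into a common feature table: an *explicit* route built from object
geometry (the D2 distribution -- a histogram of Euclidean distances between
random surface point pairs, a rigid-motion-invariant global shape signature)
and appearance (a* and b* chromatic channels of the texture in CIE L*a*b*),
and an *implicit* route that consumes precomputed convolutional-network
activations and pools them spatially. Each raw space is reduced by centered
PCA, keeping enough components to reach a variance target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr
from skimage.color import rgb2lab
from skimage.transform import resize
from sklearn.decomposition import PCA

VALID_SPACES = ("shape", "color", "shape_color", "embedding")


@dataclass(frozen=True)
class FeatureTable:
    """Raw per-object representation in one feature space."""

    object_ids: list[str]
    matrix: np.ndarray
    space_name: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != len(self.object_ids):
            raise ValueError("matrix rows must align with object_ids")
        if not np.isfinite(m).all():
            raise ValueError("feature table contains non-finite values")
        if self.space_name not in VALID_SPACES:
            raise ValueError(f"space_name must be one of {VALID_SPACES}")


def load_embedding_table(path, space_name: str = "embedding") -> FeatureTable:
    """Read a CSV/TSV with an ``object_id`` column plus numeric columns."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if "object_id" not in df.columns:
        raise ValueError("embedding table needs an 'object_id' column")
    ids = df["object_id"].astype(str).tolist()
    mat = df.drop(columns=["object_id"]).to_numpy(dtype=float)
    return FeatureTable(object_ids=ids, matrix=mat, space_name=space_name)


# ---------------------------------------------------------------------------
# D2 shape distribution


def mesh_diameter(vertices: np.ndarray) -> float:
    """Maximum pairwise vertex distance, via the convex hull for large meshes."""
    v = np.asarray(vertices, dtype=float)
    if len(v) > 500:
        from scipy.spatial import ConvexHull

        v = v[ConvexHull(v).vertices]
    return float(cdist(v, v).max())


def sample_surface_points(
    vertices: np.ndarray, faces: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform-by-area surface sampling: faces by area, barycentric within."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    total = areas.sum()
    if total <= 0:
        raise ValueError("degenerate mesh: total surface area is zero")
    idx = rng.choice(len(faces), size=n, p=areas / total)
    r1 = np.sqrt(rng.random(n))[:, None]
    r2 = rng.random(n)[:, None]
    return (1 - r1) * v0[idx] + r1 * (1 - r2) * v1[idx] + r1 * r2 * v2[idx]


def d2_shape_distribution(
    mesh, n_pairs: int = 500_000, n_bins: int = 100, rng_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """D2 histogram: distances between random surface point pairs.

    ``mesh`` is anything with ``vertices`` and (triangular) ``faces`` -- e.g.
    a ``trimesh.Trimesh``. Returns ``(hist, bin_edges)`` where ``hist`` sums
    to 1 over ``n_bins`` bins spanning [0, mesh diameter] (the support is kept
    with the histogram so D2s of differently scaled meshes stay comparable).
    """
    if n_pairs < 1 or n_bins < 1:
        raise ValueError("n_pairs and n_bins must be >= 1")
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    if faces.size == 0:
        raise ValueError("mesh has no faces")
    rng = np.random.default_rng(rng_seed)
    a = sample_surface_points(vertices, faces, n_pairs, rng)
    b = sample_surface_points(vertices, faces, n_pairs, rng)
    dists = np.linalg.norm(a - b, axis=1)
    diameter = mesh_diameter(vertices)
    hist, edges = np.histogram(dists, bins=n_bins, range=(0.0, diameter))
    return hist / hist.sum(), edges


# ---------------------------------------------------------------------------
# Color and embedding features


def color_features(texture: np.ndarray, size: int = 500) -> np.ndarray:
    """Chromatic feature vector: resized texture's a* then b* channels.

    The image is resized to ``size x size`` (bilinear), converted from sRGB
    to CIE L*a*b* (D65 white point), and the a* (green-red) and b*
    (blue-yellow) channels are flattened row-major and concatenated, keeping
    spatial color layout (no histogramming). Default length 2 * 500^2.
    """
    img = np.asarray(texture)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("color_features requires an RGB image (H x W x 3)")
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype != np.float64:
        img = img.astype(np.float64) / (255.0 if img.dtype == np.uint8 else 1.0)
    resized = resize(img, (size, size, 3), order=1, anti_aliasing=False)
    lab = rgb2lab(resized)
    return np.concatenate([lab[:, :, 1].ravel(), lab[:, :, 2].ravel()])


def pool_embedding(activation: np.ndarray) -> np.ndarray:
    """Spatially pool a conv activation tensor (H x W x C) to length H*W.

    Averages over the channel axis then flattens row-major, e.g. a
    7 x 7 x 512 max-pool activation becomes a 49-dimensional embedding.
    """
    act = np.asarray(activation, dtype=float)
    if act.ndim != 3:
        raise ValueError(f"expected a 3-axis H x W x C tensor, got ndim={act.ndim}")
    return act.mean(axis=2).ravel()


# ---------------------------------------------------------------------------
# PCA reduction


@dataclass(frozen=True)
class PCAModel:
    """Centered PCA basis with per-component explained-variance bookkeeping."""

    components: np.ndarray  # (n_components, n_raw)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-8:
            raise ValueError("explained variance ratios must be non-increasing, sum <= 1")


def fit_pca(
    table: FeatureTable,
    variance_target: float | None = None,
    n_components: int | None = None,
) -> PCAModel:
    """Fit centered PCA; pick the smallest count reaching ``variance_target``.

    Exactly one of ``variance_target`` (e.g. 0.95) or ``n_components`` must
    be given. The full spectrum is computed first, then truncated.
    """
    if (variance_target is None) == (n_components is None):
        raise ValueError("give exactly one of variance_target or n_components")
    n_obj, n_raw = table.matrix.shape
    if n_obj < 2:
        raise ValueError("PCA requires at least two objects")
    full = PCA(svd_solver="full").fit(table.matrix)
    if variance_target is not None:
        if not 0.0 < variance_target <= 1.0:
            raise ValueError("variance_target must lie in (0, 1]")
        cum = np.cumsum(full.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, len(cum))
    else:
        k = int(n_components)
        if not 1 <= k <= full.n_components_:
            raise ValueError(f"n_components={k} exceeds available rank {full.n_components_}")
    return PCAModel(
        components=full.components_[:k],
        explained_variance=full.explained_variance_[:k],
        explained_variance_ratio=full.explained_variance_ratio_[:k],
        mean=full.mean_,
        n_components=k,
    )


def project(
    table: FeatureTable, model: PCAModel, k: int | None = None, standardize: bool = True
) -> FeatureTable:
    """Project a table onto the first ``k`` principal components.

    With ``standardize=True`` (the default used upstream of the meta-MDP)
    each component score is scaled to unit sample variance, so the searcher's
    standard-normal prior over true feature values stays calibrated
    regardless of the raw feature scale. ``standardize=False`` gives raw
    scores, which preserve pairwise distances when all components are kept.
    """
    k = model.n_components if k is None else int(k)
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k={k} exceeds the model's {model.n_components} components")
    scores = (table.matrix - model.mean) @ model.components[:k].T
    if standardize:
        scores = scores / np.sqrt(model.explained_variance[:k])
    return FeatureTable(
        object_ids=list(table.object_ids), matrix=scores, space_name=table.space_name
    )


def concat_tables(a: FeatureTable, b: FeatureTable, space_name: str = "shape_color") -> FeatureTable:
    """Conjunction space: concatenate two reduced score blocks column-wise."""
    if a.object_ids != b.object_ids:
        raise ValueError("tables must cover the same objects in the same order")
    return FeatureTable(
        object_ids=list(a.object_ids),
        matrix=np.hstack([a.matrix, b.matrix]),
        space_name=space_name,
    )


# ---------------------------------------------------------------------------
# Model-agnostic gaze diagnostics


def feature_distance(u: np.ndarray, v: np.ndarray, metric: str = "euclidean") -> float:
    """Distance between two object vectors.

    ``euclidean`` for explicit (shape/color) spaces; ``spearman`` gives
    1 - rho^2 with rho the Spearman rank correlation, the convention for
    high-dimensional embeddings.
    """
    if metric == "euclidean":
        return float(np.linalg.norm(np.asarray(u) - np.asarray(v)))
    if metric == "spearman":
        rho = spearmanr(u, v).statistic
        return float(1.0 - rho**2)
    raise ValueError(f"unknown metric {metric!r}")


def distance_diagnostics(
    table: FeatureTable,
    target_ids: dict[str, str],
    fixation_records: pd.DataFrame,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Per scene/participant distance contrasts between gaze and feature space.

    ``fixation_records`` needs columns (participant_id, scene_id, ordinal,
    object_id); ``target_ids`` maps scene_id -> target object_id. For each
    (participant, scene) the summary reports: mean distance from each fixated
    object to the target vs. to the average distractor vector, and mean
    distance-to-target of fixated vs. non-fixated objects. No hypothesis
    testing is performed.
    """
    if fixation_records.empty:
        raise ValueError("empty fixation records")
    required = {"participant_id", "scene_id", "ordinal", "object_id"}
    if not required <= set(fixation_records.columns):
        raise ValueError(f"fixation records need columns {sorted(required)}")
    index = {oid: i for i, oid in enumerate(table.object_ids)}
    rows = []
    for (pid, sid), grp in fixation_records.groupby(["participant_id", "scene_id"]):
        if sid not in target_ids:
            raise ValueError(f"no target registered for scene {sid!r}")
        target = target_ids[sid]
        tvec = table.matrix[index[target]]
        fixated = [str(o) for o in grp.sort_values("ordinal")["object_id"]]
        unknown = [o for o in fixated if o not in index]
        if unknown:
            raise ValueError(f"fixation on unknown object(s) {unknown[:3]}")
        distractors = [o for o in table.object_ids if o != target]
        dvec = table.matrix[[index[o] for o in distractors]].mean(axis=0)
        d_fix_target = np.mean(
            [feature_distance(table.matrix[index[o]], tvec, metric) for o in fixated]
        )
        d_fix_distractor = np.mean(
            [feature_distance(table.matrix[index[o]], dvec, metric) for o in fixated]
        )
        fixset = set(fixated)
        fix_objs = [o for o in distractors if o in fixset]
        non_objs = [o for o in distractors if o not in fixset]
        d_fixated = (
            np.mean([feature_distance(table.matrix[index[o]], tvec, metric) for o in fix_objs])
            if fix_objs
            else np.nan
        )
        d_nonfixated = (
            np.mean([feature_distance(table.matrix[index[o]], tvec, metric) for o in non_objs])
            if non_objs
            else np.nan
        )
        rows.append(
            {
                "participant_id": pid,
                "scene_id": sid,
                "fixated_to_target": float(d_fix_target),
                "fixated_to_distractor_avg": float(d_fix_distractor),
                "fixated_objects_to_target": float(d_fixated),
                "nonfixated_objects_to_target": float(d_nonfixated),
            }
        )
    return pd.DataFrame(rows)
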