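"""Voxel-level habitat analysis: local feature maps and population K-means.

Each in-ROI voxel gets the full registry feature vector computed over its
3x3x3 (window) neighborhood intersected with the mask; voxels whose
neighborhood holds fewer than 6 masked voxels are excluded.  Voxel vectors
are pooled over all patients, standardized per feature, and clustered with
seeded K-means; the number of clusters k is chosen by the Calinski-Harabasz
score over k = 3..8 unless overridden (the replication profile fixes k = 5).
Per-patient tumor "habitats" are the distinct cluster labels present inside
that patient's ROI.

Determinism: the pooled matrix is sorted lexicographically before fitting,
so the fitted model is independent of patient order; all restarts are
seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .imaging_io import GrayLevelImage, ROIMask, VolumeImage, discretize_fixed_bins, write_volume
from .radiomics import DegenerateTextureError, FeatureRegistry, default_registry, extract_registry_features

__all__ = [
    "VoxelFeatureMap",
    "HabitatModel",
    "HabitatMap",
    "InsufficientDataError",
    "local_feature_maps",
    "fit_population_kmeans",
    "assign_habitats",
    "subcluster_count",
    "habitat_map_to_nifti",
]

MIN_NEIGHBORHOOD_VOXELS = 6
DEFAULT_K_RANGE = tuple(range(3, 9))


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class VoxelFeatureMap:
    """Per-voxel local feature vectors for one patient's ROI."""

    patient_id: object
    voxel_indices: np.ndarray  # (n, 3) int
    features: np.ndarray  # (n, n_features)
    feature_names: tuple

    def __post_init__(self):
        idx = np.asarray(self.voxel_indices, dtype=np.int64)
        f = np.asarray(self.features, dtype=float)
        if idx.ndim != 2 or idx.shape[1] != 3 or f.shape != (idx.shape[0], len(self.feature_names)):
            raise ValueError("inconsistent voxel map shapes")
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite local features")
        object.__setattr__(self, "voxel_indices", idx)
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.shape[0]


@dataclass(frozen=True)
class HabitatModel:
    k: int
    centroids: np.ndarray  # (k, n_features) in standardized space
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    seed: int
    ch_scores: dict  # k -> Calinski-Harabasz score
    feature_names: tuple
    degenerate: bool = False

    def __post_init__(self):
        c = np.asarray(self.centroids, dtype=float)
        if not self.degenerate:
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
            if np.any(d[~np.eye(len(c), dtype=bool)] < 1e-12):
                raise ValueError("centroids must be pairwise distinct")
        object.__setattr__(self, "centroids", c)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (features - self.scaler_mean) / self.scaler_sd

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "k": self.k,
                    "centroids": self.centroids.tolist(),
                    "scaler_mean": np.asarray(self.scaler_mean).tolist(),
                    "scaler_sd": np.asarray(self.scaler_sd).tolist(),
                    "seed": self.seed,
                    "ch_scores": {str(k): v for k, v in self.ch_scores.items()},
                    "feature_names": list(self.feature_names),
                    "degenerate": self.degenerate,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "HabitatModel":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["k"],
            np.array(d["centroids"]),
            np.array(d["scaler_mean"]),
            np.array(d["scaler_sd"]),
            d["seed"],
            {int(k): v for k, v in d["ch_scores"].items()},
            tuple(d["feature_names"]),
            d["degenerate"],
        )


@dataclass(frozen=True)
class HabitatMap:
    patient_id: object
    voxel_indices: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if len(self.labels) != len(self.voxel_indices):
            raise ValueError("label count must equal voxel count")


def local_feature_maps(
    volume: VolumeImage,
    mask: ROIMask,
    registry: Optional[FeatureRegistry] = None,
    window: int = 3,
    n_bins: int = 16,
    patient_id: object = None,
) -> VoxelFeatureMap:
    """Registry features over each voxel's window-neighborhood (cap mask).

    Discretization is done once over the whole ROI and reused for every
    window, so local gray levels are comparable across the tumor.  The
    default local bin count (16) keeps the bin width below the smallest
    texture scales of interest while 27-voxel histograms remain populated
    enough for co-occurrence statistics.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if registry is None:
        registry = default_registry()
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    gl = discretize_fixed_bins(volume, mask, n_bins)
    half = window // 2
    shape = volume.shape
    kept_idx = []
    rows = []
    for z, y, x in np.argwhere(m):
        sl = tuple(
            slice(max(c - half, 0), min(c + half + 1, s)) for c, s in zip((z, y, x), shape)
        )
        sub_mask = m[sl]
        if sub_mask.sum() < MIN_NEIGHBORHOOD_VOXELS:
            continue
        sub_vol = VolumeImage(volume.data[sl], volume.spacing)
        sub_gl = GrayLevelImage(np.where(sub_mask, gl.data[sl], 0), n_bins)
        try:
            vec = extract_registry_features(
                sub_vol, ROIMask(sub_mask.astype(np.int8)), registry, gray=sub_gl
            )
        except DegenerateTextureError:
            continue  # e.g. isolated corner voxels with no adjacent pair
        kept_idx.append((z, y, x))
        rows.append([vec[n] for n in registry.names])
    if not rows:
        raise InsufficientDataError("no voxel satisfies the neighborhood minimum")
    return VoxelFeatureMap(
        patient_id, np.array(kept_idx), np.array(rows), tuple(registry.names)
    )


def fit_population_kmeans(
    maps: Sequence[VoxelFeatureMap],
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    seed: int = 0,
    k_override: Optional[int] = None,
) -> HabitatModel:
    """Pool all patients' voxels, standardize, and fit seeded K-means.

    K-means uses k-means++ with 10 restarts, 300-iteration cap and 1e-4
    relative tolerance for every k in *k_range*; the returned model is the
    Calinski-Harabasz argmax (first k on ties) unless *k_override* fixes k,
    in which case all scores are still reported.
    """
    k_range = sorted(k_range)
    pooled = np.vstack([m.features for m in maps])
    names = maps[0].feature_names
    if any(m.feature_names != names for m in maps):
        raise ValueError("voxel maps disagree on feature space")
    if pooled.shape[0] < max(k_range) * 10:
        raise InsufficientDataError(
            f"pooled voxel count {pooled.shape[0]} < {max(k_range) * 10}"
        )
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (pooled - mean) / sd_safe
    # canonical row order -> patient-order-independent fits
    z = z[np.lexsort(z.T[::-1])]
    if np.allclose(z, z[0], atol=1e-12):
        return HabitatModel(
            k_range[0],
            np.repeat(z[:1], k_range[0], axis=0),
            mean,
            sd_safe,
            seed,
            {},
            names,
            degenerate=True,
        )
    fits = {}
    scores = {}
    for k in k_range:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=10,
            max_iter=300,
            tol=1e-4,
            random_state=seed,
        ).fit(z)
        fits[k] = km
        scores[k] = float(calinski_harabasz_score(z, km.labels_))
    if k_override is not None:
        if k_override not in fits:
            raise ValueError(f"k_override {k_override} outside explored range")
        best_k = k_override
    else:
        best_k = max(scores, key=lambda k: (scores[k], -k))
    return HabitatModel(
        best_k, fits[best_k].cluster_centers_, mean, sd_safe, seed, scores, names
    )


def assign_habitats(vmap: VoxelFeatureMap, model: HabitatModel) -> HabitatMap:
    """Label each voxel by its nearest centroid (ties -> lowest label)."""
    if vmap.feature_names != model.feature_names:
        raise ValueError("voxel map features do not match the model")
    z = model.transform(vmap.features)
    d2 = ((z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)  # argmin takes the first minimum: lowest index
    return HabitatMap(vmap.patient_id, vmap.voxel_indices, labels.astype(np.int64))


def subcluster_count(hm: HabitatMap) -> int:
    """Number of distinct habitats present in one patient's ROI."""
    if len(hm.labels) == 0:
        raise ValueError("empty habitat map")
    return int(len(np.unique(hm.labels)))


def habitat_map_to_nifti(hm: HabitatMap, shape, spacing, path) -> None:
    """Export labels+1 inside the ROI (0 outside) as a NIfTI label volume."""
    out = np.zeros(shape, dtype=np.int16)
    out[tuple(hm.voxel_indices.T)] = hm.labels + 1
    write_volume(path, out, spacing)
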