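"""Heterogeneity-related radiomic features over 3D tumor ROIs.

Implements the 42-feature heterogeneity registry: 9 first-order features on
the in-mask intensity distribution plus 33 texture features from gray-level
co-occurrence (GLCM), run-length (GLRLM), size-zone (GLSZM), neighborhood
gray-tone difference (NGTDM) and dependence (GLDM) matrices, all computed in
3D on discretized gray levels.

Conventions (fixed so results are exactly testable):

* GLCM: distance-1 voxel offsets over the 13 unique 3D directions; each
  direction's matrix is symmetric (both voxel orders counted), restricted to
  pairs with both endpoints in the mask, normalized to sum 1; features are
  computed per direction and averaged over directions that contain at least
  one valid pair.
* GLRLM: maximal same-level runs per direction (13 directions, masked-out
  voxels break runs), features averaged over directions.
* GLSZM: zones are 26-connected components of equal gray level inside the
  mask.
* NGTDM: per-voxel average gray tone over the 26-neighborhood intersected
  with the mask; voxels without any masked neighbor are excluded.
* GLDM: dependence of a voxel = 1 + number of 26-neighbors in the mask with
  the same gray level (alpha = 0).

Every feature carries a heterogeneity sign: +1 when larger values indicate a
more heterogeneous tumor (dispersion, entropies, non-uniformities), -1 when
larger values indicate homogeneity (uniformity, energy, inverse difference
moment, correlation, coarseness, long-run emphasis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_io import (
    GrayLevelImage,
    ROIMask,
    VolumeImage,
    discretize_fixed_bins,
    discretize_fixed_width,
)

__all__ = [
    "FeatureDef",
    "FeatureRegistry",
    "DegenerateTextureError",
    "default_registry",
    "compute_first_order",
    "compute_glcm_features",
    "compute_higher_order_features",
    "extract_registry_features",
    "glcm_matrices",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
    "DIRECTIONS_13",
]


class DegenerateTextureError(ValueError):
    """Texture matrices cannot be formed (e.g. single-voxel ROI)."""


# The 13 unique direction offsets of the 26-neighborhood (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class FeatureDef:
    name: str
    family: str  # first_order | glcm | glrlm | glszm | ngtdm | gldm
    sign: int  # +1 heterogeneity-positive, -1 heterogeneity-negative
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, signed list of heterogeneity features."""

    entries: tuple[FeatureDef, ...]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        for e in self.entries:
            if e.sign not in (+1, -1):
                raise ValueError(f"{e.name}: sign must be +1 or -1")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def signs(self) -> dict[str, int]:
        return {e.name: e.sign for e in self.entries}

    @property
    def families(self) -> set[str]:
        return {e.family for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {"name": e.name, "family": e.family, "sign": e.sign, "params": e.params}
                    for e in self.entries
                ],
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "FeatureRegistry":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(tuple(FeatureDef(r["name"], r["family"], r["sign"], r.get("params", {})) for r in raw))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                [
                    {"name": e.name, "family": e.family, "sign": e.sign, "params": e.params}
                    for e in self.entries
                ],
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "FeatureRegistry":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(tuple(FeatureDef(r["name"], r["family"], r["sign"], r.get("params", {})) for r in raw))


def default_registry() -> FeatureRegistry:
    """The default 42-entry heterogeneity registry (9 first-order + 33 texture)."""
    fo = [
        ("firstorder_variance", +1),
        ("firstorder_standard_deviation", +1),
        ("firstorder_mean_absolute_deviation", +1),
        ("firstorder_robust_mean_absolute_deviation", +1),
        ("firstorder_interquartile_range", +1),
        ("firstorder_range", +1),
        ("firstorder_entropy", +1),
        ("firstorder_uniformity", -1),
        ("firstorder_energy", -1),
    ]
    glcm = [
        ("glcm_contrast", +1),
        ("glcm_dissimilarity", +1),
        ("glcm_joint_entropy", +1),
        ("glcm_difference_entropy", +1),
        ("glcm_sum_entropy", +1),
        ("glcm_difference_variance", +1),
        ("glcm_cluster_shade", +1),
        ("glcm_cluster_prominence", +1),
        ("glcm_correlation", -1),
        ("glcm_inverse_difference_moment", -1),
        ("glcm_inverse_difference", -1),
        ("glcm_joint_energy", -1),
    ]
    glrlm = [
        ("glrlm_gray_level_non_uniformity", +1),
        ("glrlm_run_length_non_uniformity", +1),
        ("glrlm_run_entropy", +1),
        ("glrlm_gray_level_variance", +1),
        ("glrlm_run_variance", +1),
        ("glrlm_run_percentage", +1),
        ("glrlm_long_run_emphasis", -1),
    ]
    glszm = [
        ("glszm_gray_level_non_uniformity", +1),
        ("glszm_size_zone_non_uniformity", +1),
        ("glszm_zone_entropy", +1),
        ("glszm_gray_level_variance", +1),
        ("glszm_zone_variance", +1),
        ("glszm_zone_percentage", +1),
    ]
    ngtdm = [
        ("ngtdm_contrast", +1),
        ("ngtdm_busyness", +1),
        ("ngtdm_coarseness", -1),
    ]
    gldm = [
        ("gldm_dependence_non_uniformity", +1),
        ("gldm_dependence_entropy", +1),
        ("gldm_gray_level_non_uniformity", +1),
        ("gldm_dependence_variance", +1),
        ("gldm_small_dependence_emphasis", +1),
    ]
    entries = []
    for family, items in [
        ("first_order", fo),
        ("glcm", glcm),
        ("glrlm", glrlm),
        ("glszm", glszm),
        ("ngtdm", ngtdm),
        ("gldm", gldm),
    ]:
        params = {"distance": 1} if family in ("glcm", "glrlm", "gldm") else {}
        entries.extend(FeatureDef(name, family, sign, dict(params)) for name, sign in items)
    reg = FeatureRegistry(tuple(entries))
    assert len(reg) == 42
    return reg


# ---------------------------------------------------------------------------
# helpers


def _neighbor(a: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """Return b with b[v] = a[v + d], padded with *fill* outside the grid."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for axis, off in enumerate(d):
        n = a.shape[axis]
        if off >= 0:
            dst.append(slice(0, n - off))
            src.append(slice(off, n))
        else:
            dst.append(slice(-off, n))
            src.append(slice(0, n + off))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# first order


def compute_first_order(volume: VolumeImage, mask: ROIMask, gl: GrayLevelImage) -> dict[str, float]:
    """First-order intensity-dispersion features.

    Dispersion statistics (variance, SD, MAD, robust MAD, IQR, range,
    energy) are computed on the raw in-mask intensities (population
    moments); entropy and uniformity on the gray-level histogram of *gl*
    with probabilities normalized to sum 1.
    """
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    x = volume.data[m]
    mean = x.mean()
    var = float(((x - mean) ** 2).mean())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    mid = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0
    levels = gl.data[m]
    counts = np.bincount(levels, minlength=gl.n_levels + 1)[1:]
    p = counts / counts.sum()
    return {
        "firstorder_variance": var,
        "firstorder_standard_deviation": float(np.sqrt(var)),
        "firstorder_mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "firstorder_robust_mean_absolute_deviation": rmad,
        "firstorder_interquartile_range": float(p75 - p25),
        "firstorder_range": float(x.max() - x.min()),
        "firstorder_entropy": _entropy2(p),
        "firstorder_uniformity": float((p**2).sum()),
        # mean squared intensity: comparable across ROI sizes
        "firstorder_energy": float((x**2).mean()),
    }


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrices(gl: GrayLevelImage, distance: int = 1) -> np.ndarray:
    """Stack of symmetric normalized GLCMs, one per 13 directions.

    Directions with no valid in-mask pair yield an all-zero matrix.
    """
    a = gl.data
    ng = gl.n_levels
    mats = np.zeros((len(DIRECTIONS_13), ng, ng))
    for k, d in enumerate(DIRECTIONS_13):
        off = tuple(distance * c for c in d)
        b = _neighbor(a, off, 0)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        i = a[valid] - 1
        j = b[valid] - 1
        np.add.at(mats[k], (i, j), 1.0)
        np.add.at(mats[k], (j, i), 1.0)
        mats[k] /= mats[k].sum()
    return mats


_GLCM_CACHE: dict[int, tuple] = {}


def _glcm_grids(ng: int) -> tuple:
    """Cached index grids and one-hot marginal projectors for Ng levels."""
    if ng not in _GLCM_CACHE:
        idx = np.arange(1, ng + 1, dtype=float)
        I = np.repeat(idx[:, None], ng, axis=1)
        J = I.T
        diff = np.abs(I - J).astype(int)  # 0..ng-1
        summ = (I + J).astype(int) - 2  # 0..2ng-2
        M_diff = np.zeros((ng * ng, ng))
        M_diff[np.arange(ng * ng), diff.ravel()] = 1.0
        M_sum = np.zeros((ng * ng, 2 * ng - 1))
        M_sum[np.arange(ng * ng), summ.ravel()] = 1.0
        _GLCM_CACHE[ng] = (idx, I, J, M_diff, M_sum)
    return _GLCM_CACHE[ng]


def _entropy2_rows(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -t.sum(axis=1)


def _glcm_features_stack(P: np.ndarray) -> dict[str, np.ndarray]:
    """All 12 GLCM features for a (D, Ng, Ng) stack of normalized matrices."""
    d, ng, _ = P.shape
    idx, I, J, M_diff, M_sum = _glcm_grids(ng)
    flat = P.reshape(d, -1)
    px = P.sum(axis=2)
    mu = (idx[None, :] * px).sum(axis=1)
    sigma2 = (((idx[None, :] - mu[:, None]) ** 2) * px).sum(axis=1)
    p_diff = flat @ M_diff
    p_sum = flat @ M_sum
    k_diff = np.arange(ng, dtype=float)
    da = (k_diff[None, :] * p_diff).sum(axis=1)
    ij_shift = I[None] + J[None] - 2 * mu[:, None, None]
    with np.errstate(invalid="ignore"):
        corr = np.where(
            sigma2 <= 1e-12,
            1.0,
            ((I * J)[None] * P).sum(axis=(1, 2)) - mu * mu,
        )
        corr = np.where(sigma2 <= 1e-12, 1.0, corr / np.where(sigma2 <= 1e-12, 1.0, sigma2))
    return {
        "glcm_contrast": (((I - J) ** 2)[None] * P).sum(axis=(1, 2)),
        "glcm_dissimilarity": (np.abs(I - J)[None] * P).sum(axis=(1, 2)),
        "glcm_joint_entropy": _entropy2_rows(flat),
        "glcm_difference_entropy": _entropy2_rows(p_diff),
        "glcm_sum_entropy": _entropy2_rows(p_sum),
        "glcm_difference_variance": (
            (k_diff[None, :] - da[:, None]) ** 2 * p_diff
        ).sum(axis=1),
        "glcm_cluster_shade": (ij_shift**3 * P).sum(axis=(1, 2)),
        "glcm_cluster_prominence": (ij_shift**4 * P).sum(axis=(1, 2)),
        "glcm_correlation": corr,
        "glcm_inverse_difference_moment": ((1.0 / (1.0 + (I - J) ** 2))[None] * P).sum(axis=(1, 2)),
        "glcm_inverse_difference": ((1.0 / (1.0 + np.abs(I - J)))[None] * P).sum(axis=(1, 2)),
        "glcm_joint_energy": (flat**2).sum(axis=1),
    }


def compute_glcm_features(
    gl: GrayLevelImage, mask: ROIMask, distance: int = 1
) -> dict[str, float]:
    """Direction-averaged GLCM features (13 symmetric 3D directions)."""
    mats = glcm_matrices(gl, distance)
    nonempty = mats[mats.sum(axis=(1, 2)) > 0]
    if len(nonempty) == 0:
        raise DegenerateTextureError("no valid voxel pair in any direction")
    per_dir = _glcm_features_stack(nonempty)
    return {k: float(v.mean()) for k, v in per_dir.items()}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(gl: GrayLevelImage, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts P[level-1, length-1] for one direction.

    Runs are maximal sequences of equal gray level along *direction*;
    out-of-mask voxels break runs.
    """
    a = gl.data
    valid = a > 0
    max_len = int(np.ceil(np.sqrt(sum((c * s) ** 2 for c, s in zip(direction, a.shape))))) + 1
    neg = tuple(-c for c in direction)
    prev_same = (_neighbor(a, neg, 0) == a) & _neighbor(valid, neg, False)
    start = valid & ~prev_same
    starts = np.argwhere(start)
    if starts.size == 0:
        return np.zeros((gl.n_levels, 1))
    levels = a[start]
    lengths = np.ones(len(starts), dtype=np.int64)
    alive = np.ones(len(starts), dtype=bool)
    k = 1
    while alive.any():
        off = tuple(k * c for c in direction)
        nb_val = _neighbor(a, off, 0)
        eq = nb_val[tuple(starts.T)] == levels
        alive &= eq
        lengths[alive] += 1
        k += 1
        if k > max_len:  # pragma: no cover - safety bound
            break
    P = np.zeros((gl.n_levels, int(lengths.max())))
    np.add.at(P, (levels - 1, lengths - 1), 1.0)
    return P


def _marginal_variance(p_marg: np.ndarray, values: np.ndarray) -> float:
    mu = float((values * p_marg).sum())
    return float(((values - mu) ** 2 * p_marg).sum())


def _glrlm_features_one(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = P.sum()
    p = P / nr
    r_i = P.sum(axis=1)
    r_l = P.sum(axis=0)
    lengths = np.arange(1, P.shape[1] + 1, dtype=float)
    levels = np.arange(1, P.shape[0] + 1, dtype=float)
    return {
        "glrlm_gray_level_non_uniformity": float((r_i**2).sum() / nr),
        "glrlm_run_length_non_uniformity": float((r_l**2).sum() / nr),
        "glrlm_run_entropy": _entropy2(p.ravel()),
        "glrlm_gray_level_variance": _marginal_variance(r_i / nr, levels),
        "glrlm_run_variance": _marginal_variance(r_l / nr, lengths),
        "glrlm_run_percentage": float(nr / n_voxels),
        "glrlm_long_run_emphasis": float((lengths**2 * (r_l / nr)).sum()),
    }


def _glrlm_features(gl: GrayLevelImage, n_voxels: int) -> dict[str, float]:
    per_dir = [_glrlm_features_one(glrlm_matrix(gl, d), n_voxels) for d in DIRECTIONS_13]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(gl: GrayLevelImage) -> np.ndarray:
    """Size-zone counts P[level-1, size-1]; zones are 26-connected components."""
    a = gl.data
    zone_sizes: list[tuple[int, int]] = []
    for lv in np.unique(a[a > 0]):
        lab, n = ndimage.label(a == lv, structure=_CONN26)
        sizes = np.bincount(lab.ravel())[1:]
        zone_sizes.extend((int(lv), int(s)) for s in sizes)
    max_size = max(s for _, s in zone_sizes)
    P = np.zeros((gl.n_levels, max_size))
    for lv, s in zone_sizes:
        P[lv - 1, s - 1] += 1.0
    return P


def _glszm_features(gl: GrayLevelImage, n_voxels: int) -> dict[str, float]:
    P = glszm_matrix(gl)
    nz = P.sum()
    p = P / nz
    z_i = P.sum(axis=1)
    z_s = P.sum(axis=0)
    sizes = np.arange(1, P.shape[1] + 1, dtype=float)
    levels = np.arange(1, P.shape[0] + 1, dtype=float)
    return {
        "glszm_gray_level_non_uniformity": float((z_i**2).sum() / nz),
        "glszm_size_zone_non_uniformity": float((z_s**2).sum() / nz),
        "glszm_zone_entropy": _entropy2(p.ravel()),
        "glszm_gray_level_variance": _marginal_variance(z_i / nz, levels),
        "glszm_zone_variance": _marginal_variance(z_s / nz, sizes),
        "glszm_zone_percentage": float(nz / n_voxels),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(gl: GrayLevelImage) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) over voxels with >= 1 masked 26-neighbor.

    Returns (n per level, s per level, number of included voxels); s_i is the
    summed absolute difference between level i and the neighborhood average
    gray tone.
    """
    a = gl.data.astype(float)
    valid = gl.data > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nsum = ndimage.correlate(a * valid, kernel, mode="constant")
    ncount = ndimage.correlate(valid.astype(float), kernel, mode="constant")
    incl = valid & (ncount > 0)
    avg = np.zeros_like(a)
    avg[incl] = nsum[incl] / ncount[incl]
    ng = gl.n_levels
    n = np.zeros(ng)
    s = np.zeros(ng)
    lv = gl.data[incl]
    dif = np.abs(a[incl] - avg[incl])
    np.add.at(n, lv - 1, 1.0)
    np.add.at(s, lv - 1, dif)
    return n, s, int(incl.sum())


def _ngtdm_features(gl: GrayLevelImage) -> dict[str, float]:
    n, s, nvp = ngtdm_table(gl)
    if nvp == 0:
        raise DegenerateTextureError("no voxel has a masked neighbor")
    p = n / nvp
    present = p > 0
    levels = np.arange(1, len(p) + 1, dtype=float)
    ngp = int(present.sum())
    if ngp > 1:
        pi = p[present]
        li = levels[present]
        cross = float((pi[:, None] * pi[None, :] * (li[:, None] - li[None, :]) ** 2).sum())
        contrast = cross / (ngp * (ngp - 1)) * (s.sum() / nvp)
        denom = float(np.abs(li[:, None] * pi[:, None] - li[None, :] * pi[None, :]).sum())
        busy_num = float((p * s).sum())
        busyness = busy_num / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    ps = float((p * s).sum())
    coarseness = min(1.0 / ps, 1e6) if ps > 0 else 1e6
    return {
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_coarseness": coarseness,
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(gl: GrayLevelImage) -> np.ndarray:
    """Dependence counts P[level-1, d-1], d = 1 + #same-level 26-neighbors."""
    a = gl.data
    valid = a > 0
    dep = np.zeros(a.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for off in (d, tuple(-c for c in d)):
            same = (_neighbor(a, off, 0) == a) & _neighbor(valid, off, False)
            dep += same
    dep += 1
    P = np.zeros((gl.n_levels, 27))
    np.add.at(P, (a[valid] - 1, dep[valid] - 1), 1.0)
    return P


def _gldm_features(gl: GrayLevelImage, n_voxels: int) -> dict[str, float]:
    P = gldm_matrix(gl)
    nd = P.sum()
    p = P / nd
    d_i = P.sum(axis=1)
    d_d = P.sum(axis=0)
    deps = np.arange(1, P.shape[1] + 1, dtype=float)
    return {
        "gldm_dependence_non_uniformity": float((d_d**2).sum() / nd),
        "gldm_dependence_entropy": _entropy2(p.ravel()),
        "gldm_gray_level_non_uniformity": float((d_i**2).sum() / nd),
        "gldm_dependence_variance": _marginal_variance(d_d / nd, deps),
        "gldm_small_dependence_emphasis": float((P / deps[None, :] ** 2).sum() / nd),
    }


def compute_higher_order_features(gl: GrayLevelImage, mask: ROIMask) -> dict[str, float]:
    """GLRLM + GLSZM + NGTDM + GLDM features for one ROI."""
    nv = mask.n_voxels
    if nv == 0:
        raise ValueError("empty mask")
    out: dict[str, float] = {}
    out.update(_glrlm_features(gl, nv))
    out.update(_glszm_features(gl, nv))
    out.update(_ngtdm_features(gl))
    out.update(_gldm_features(gl, nv))
    return out


# ---------------------------------------------------------------------------
# assembly


def extract_registry_features(
    volume: VolumeImage,
    mask: ROIMask,
    registry: FeatureRegistry | None = None,
    n_bins: int = 32,
    gray: GrayLevelImage | None = None,
    bin_width: float | None = None,
) -> dict[str, float]:
    """Complete signed feature vector for one ROI, in registry order.

    Discretization uses *n_bins* equal-width bins over the masked range by
    default; passing *bin_width* switches to fixed-width levels, the
    recommended setting for cohort-level features that must be comparable
    across patients.  A precomputed :class:`GrayLevelImage` may be passed
    via *gray* (used by the local-window pipeline, which discretizes once
    over the whole ROI).
    """
    if registry is None:
        registry = default_registry()
    if not mask.data.any():
        raise ValueError("empty mask")
    if gray is not None:
        gl = gray
    elif bin_width is not None:
        gl = discretize_fixed_width(volume, mask, bin_width)
    else:
        gl = discretize_fixed_bins(volume, mask, n_bins)
    pool: dict[str, float] = {}
    fams = registry.families
    if "first_order" in fams:
        pool.update(compute_first_order(volume, mask, gl))
    if "glcm" in fams:
        dist = next(
            (e.params.get("distance", 1) for e in registry.entries if e.family == "glcm"), 1
        )
        pool.update(compute_glcm_features(gl, mask, distance=dist))
    if fams & {"glrlm", "glszm", "ngtdm", "gldm"}:
        pool.update(compute_higher_order_features(gl, mask))
    vec = {}
    for e in registry.entries:
        if e.name not in pool:
            raise KeyError(f"registry feature {e.name!r} was not computed")
        v = pool[e.name]
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite value for {e.name}")
        vec[e.name] = float(v)
    return vec
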