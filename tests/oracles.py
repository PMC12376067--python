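"""Independent brute-force oracles for the texture-matrix machinery.

Everything here is written as plain Python loops over voxels, deliberately
avoiding the vectorized code paths in the package: these functions define
what the fast implementations must reproduce.
"""

import numpy as np

ALL_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
DIRS_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def brute_glcm(gl: np.ndarray, ng: int, direction, distance=1) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by explicit pair listing."""
    off = tuple(distance * c for c in direction)
    P = np.zeros((ng, ng))
    nz, ny, nx = gl.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = gl[z, y, x]
                if a == 0:
                    continue
                z2, y2, x2 = z + off[0], y + off[1], x + off[2]
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                b = gl[z2, y2, x2]
                if b == 0:
                    continue
                P[a - 1, b - 1] += 1
                P[b - 1, a - 1] += 1
    s = P.sum()
    return P / s if s > 0 else P


def brute_glcm_features(P: np.ndarray) -> dict:
    """Scalar-loop GLCM feature formulas over one normalized matrix."""
    ng = P.shape[0]
    mu = sum((i + 1) * P[i, j] for i in range(ng) for j in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    feats = {
        "glcm_contrast": 0.0,
        "glcm_dissimilarity": 0.0,
        "glcm_joint_entropy": 0.0,
        "glcm_cluster_shade": 0.0,
        "glcm_cluster_prominence": 0.0,
        "glcm_inverse_difference_moment": 0.0,
        "glcm_inverse_difference": 0.0,
        "glcm_joint_energy": 0.0,
    }
    p_diff = np.zeros(ng)
    p_sum = np.zeros(2 * ng - 1)
    cross = 0.0
    for i in range(ng):
        for j in range(ng):
            p = P[i, j]
            d = abs(i - j)
            feats["glcm_contrast"] += (i - j) ** 2 * p
            feats["glcm_dissimilarity"] += d * p
            if p > 0:
                feats["glcm_joint_entropy"] -= p * np.log2(p)
            feats["glcm_cluster_shade"] += (i + j + 2 - 2 * mu) ** 3 * p
            feats["glcm_cluster_prominence"] += (i + j + 2 - 2 * mu) ** 4 * p
            feats["glcm_inverse_difference_moment"] += p / (1 + (i - j) ** 2)
            feats["glcm_inverse_difference"] += p / (1 + d)
            feats["glcm_joint_energy"] += p**2
            p_diff[d] += p
            p_sum[i + j] += p
            cross += (i + 1) * (j + 1) * p
    feats["glcm_difference_entropy"] = -sum(
        p * np.log2(p) for p in p_diff if p > 0
    )
    feats["glcm_sum_entropy"] = -sum(p * np.log2(p) for p in p_sum if p > 0)
    da = sum(k * p_diff[k] for k in range(ng))
    feats["glcm_difference_variance"] = sum(
        (k - da) ** 2 * p_diff[k] for k in range(ng)
    )
    feats["glcm_correlation"] = (
        1.0 if sigma2 <= 1e-12 else (cross - mu * mu) / sigma2
    )
    return feats


def brute_glrlm(gl: np.ndarray, ng: int, direction) -> np.ndarray:
    """Run-length matrix by walking every line voxel by voxel."""
    nz, ny, nx = gl.shape
    runs = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if gl[z, y, x] == 0:
                    continue
                pz, py, px = z - direction[0], y - direction[1], x - direction[2]
                if (
                    0 <= pz < nz
                    and 0 <= py < ny
                    and 0 <= px < nx
                    and gl[pz, py, px] == gl[z, y, x]
                ):
                    continue  # not a run start
                length = 1
                cz, cy, cx = z, y, x
                while True:
                    cz, cy, cx = cz + direction[0], cy + direction[1], cx + direction[2]
                    if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
                        break
                    if gl[cz, cy, cx] != gl[z, y, x]:
                        break
                    length += 1
                runs.append((gl[z, y, x], length))
    max_len = max(l for _, l in runs)
    P = np.zeros((ng, max_len))
    for lv, l in runs:
        P[lv - 1, l - 1] += 1
    return P


def brute_zone_count(gl: np.ndarray) -> int:
    """Number of 26-connected equal-level zones, by flood fill."""
    seen = np.zeros(gl.shape, dtype=bool)
    n_zones = 0
    nz, ny, nx = gl.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if gl[z, y, x] == 0 or seen[z, y, x]:
                    continue
                n_zones += 1
                stack = [(z, y, x)]
                seen[z, y, x] = True
                lv = gl[z, y, x]
                while stack:
                    cz, cy, cx = stack.pop()
                    for dz, dy, dx in ALL_26:
                        w = (cz + dz, cy + dy, cx + dx)
                        if (
                            0 <= w[0] < nz
                            and 0 <= w[1] < ny
                            and 0 <= w[2] < nx
                            and not seen[w]
                            and gl[w] == lv
                        ):
                            seen[w] = True
                            stack.append(w)
    return n_zones


def brute_first_order_histogram(levels: np.ndarray, ng: int) -> tuple[float, float]:
    """(entropy bits, uniformity) of a gray-level sample by direct counting."""
    counts = {}
    for v in levels:
        counts[v] = counts.get(v, 0) + 1
    n = len(levels)
    ent = 0.0
    unif = 0.0
    for c in counts.values():
        p = c / n
        ent -= p * np.log2(p)
        unif += p * p
    return ent, unif
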