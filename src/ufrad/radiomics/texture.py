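"""Gray-level co-occurrence and run-length texture features (162 values).

Intensities are discretized to a fixed bin count over the in-mask range.
GLCM features (22 descriptors) are computed per in-plane offset at
distance 1 — 0, 45, 90 and 135 degrees within the axial plane — from the
symmetric normalized matrix, plus once more from the direction-averaged
matrix (22 x 5 = 110).  GLRLM features (13 descriptors) are computed per
direction (13 x 4 = 52); voxels outside the mask break runs.
"""

from __future__ import annotations

import numpy as np

from ufrad.radiomics.preprocess import discretize

# in-plane (dz, dy, dx) offsets at distance 1
OFFSETS = {
    "a0": (0, 0, 1),
    "a45": (0, 1, 1),
    "a90": (0, 1, 0),
    "a135": (0, 1, -1),
}

GLCM_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "idm",
    "idmn",
    "id",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_entropy",
    "sum_squares",
)

GLRLM_NAMES = (
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lglre",
    "hglre",
    "srlgle",
    "srhgle",
    "lrlgle",
    "lrhgle",
    "glv",
    "rlv",
)


def glcm_matrix(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int], n_levels: int
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one offset.

    ``levels`` holds integer gray levels (1..n_levels) inside the mask.
    Each ordered voxel pair (v, v+offset) with both ends in the mask is
    counted in both directions; the matrix is normalized to sum 1 (all
    zeros if the offset yields no pair).
    """
    dz, dy, dx = offset
    nz, ny, nx = levels.shape
    src = [slice(max(0, -d), n - max(0, d)) for d, n in ((dz, nz), (dy, ny), (dx, nx))]
    tgt = [slice(max(0, d), n - max(0, -d)) for d, n in ((dz, nz), (dy, ny), (dx, nx))]
    m_src = mask[tuple(src)]
    m_tgt = mask[tuple(tgt)]
    valid = m_src & m_tgt
    i = levels[tuple(src)][valid] - 1
    j = levels[tuple(tgt)][valid] - 1
    counts = np.zeros((n_levels, n_levels))
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """22 descriptors of a normalized symmetric GLCM."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - ux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - uy) ** 2 * py)))

    # diagonal / cross-diagonal marginals
    k_diff = np.abs(ii - jj)
    p_diff = np.array([P[k_diff == k].sum() for k in range(ng)])
    k_sum = ii + jj
    p_sum = np.array([P[k_sum == k].sum() for k in range(2, 2 * ng + 1)])

    def _ent(p):
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p))) if p.size else 0.0

    hxy = _ent(P.ravel())
    hx, hy = _ent(px), _ent(py)
    outer = np.outer(px, py)
    nz = (P > 0) & (outer > 0)
    hxy1 = float(-np.sum(P[nz] * np.log2(outer[nz])))
    nz2 = outer > 0
    hxy2 = float(-np.sum(outer[nz2] * np.log2(outer[nz2])))

    autocorr = float(np.sum(P * ii * jj))
    corr = 1.0 if sx * sy == 0 else (autocorr - ux * uy) / (sx * sy)
    diff_avg = float(np.sum(np.arange(ng) * p_diff))
    imc1 = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off_diag = k_diff > 0
    return {
        "autocorrelation": autocorr,
        "joint_average": ux,
        "cluster_prominence": float(np.sum(P * (ii + jj - ux - uy) ** 4)),
        "cluster_shade": float(np.sum(P * (ii + jj - ux - uy) ** 3)),
        "cluster_tendency": float(np.sum(P * (ii + jj - ux - uy) ** 2)),
        "contrast": float(np.sum(P * (ii - jj) ** 2)),
        "correlation": float(corr),
        "difference_average": diff_avg,
        "difference_entropy": _ent(p_diff),
        "difference_variance": float(
            np.sum((np.arange(ng) - diff_avg) ** 2 * p_diff)
        ),
        "joint_energy": float(np.sum(P**2)),
        "joint_entropy": hxy,
        "imc1": float(imc1),
        "imc2": imc2,
        "idm": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "idmn": float(np.sum(P / (1.0 + ((ii - jj) / ng) ** 2))),
        "id": float(np.sum(P / (1.0 + k_diff))),
        "idn": float(np.sum(P / (1.0 + k_diff / ng))),
        "inverse_variance": float(
            np.sum(P[off_diag] / (ii - jj)[off_diag] ** 2)
        ),
        "maximum_probability": float(P.max()),
        "sum_entropy": _ent(p_sum),
        "sum_squares": float(np.sum(P * (ii - ux) ** 2)),
    }


def _direction_lines(levels: np.ndarray, key: str) -> list[np.ndarray]:
    """All 1D lines of the volume along one in-plane direction."""
    nz, ny, nx = levels.shape
    if key == "a0":
        return list(levels.reshape(nz * ny, nx))
    if key == "a90":
        return list(np.transpose(levels, (0, 2, 1)).reshape(nz * nx, ny))
    lines = []
    for z in range(nz):
        sl = levels[z] if key == "a45" else levels[z, :, ::-1]
        for off in range(-ny + 1, nx):
            lines.append(np.diagonal(sl, offset=off))
    return lines


def glrlm_matrix(levels: np.ndarray, key: str, n_levels: int) -> np.ndarray:
    """Run-length matrix R[gray level, run length] for one direction."""
    lines = _direction_lines(levels, key)
    max_len = max(levels.shape)
    # concatenate lines with 0 separators, then one RLE pass
    sep = np.zeros(1, dtype=levels.dtype)
    flat = np.concatenate([np.concatenate([ln, sep]) for ln in lines])
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    vals = flat[starts]
    lens = ends - starts
    keep = vals > 0
    R = np.zeros((n_levels, max_len))
    np.add.at(R, (vals[keep] - 1, np.minimum(lens[keep], max_len) - 1), 1.0)
    return R


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    """13 run-length descriptors."""
    nr = R.sum()
    if nr == 0:
        return {name: 0.0 for name in GLRLM_NAMES}
    p = R / nr
    g = np.arange(1, R.shape[0] + 1)[:, None]
    l = np.arange(1, R.shape[1] + 1)[None, :]
    mu_g = float(np.sum(p * g))
    mu_l = float(np.sum(p * l))
    return {
        "sre": float(np.sum(p / l**2)),
        "lre": float(np.sum(p * l**2)),
        "gln": float(np.sum(R.sum(axis=1) ** 2) / nr),
        "rln": float(np.sum(R.sum(axis=0) ** 2) / nr),
        "rp": float(nr / n_voxels),
        "lglre": float(np.sum(p / g**2)),
        "hglre": float(np.sum(p * g**2)),
        "srlgle": float(np.sum(p / (g**2 * l**2))),
        "srhgle": float(np.sum(p * g**2 / l**2)),
        "lrlgle": float(np.sum(p * l**2 / g**2)),
        "lrhgle": float(np.sum(p * g**2 * l**2)),
        "glv": float(np.sum(p * (g - mu_g) ** 2)),
        "rlv": float(np.sum(p * (l - mu_l) ** 2)),
    }


def extract_texture(
    vol: np.ndarray, mask: np.ndarray, n_bins: int = 32
) -> dict[str, float]:
    """162 texture features: GLCM 22 x (4 offsets + average), GLRLM 13 x 4."""
    mask = np.asarray(mask, dtype=bool)
    levels = discretize(vol, mask, n_bins)
    out: dict[str, float] = {}
    matrices = {key: glcm_matrix(levels, mask, off, n_bins) for key, off in OFFSETS.items()}
    for key, P in matrices.items():
        for name, value in glcm_features(P).items():
            out[f"glcm_{name}_{key}"] = value
    avg = np.mean(list(matrices.values()), axis=0)
    total = avg.sum()
    if total > 0:
        avg = avg / total
    for name, value in glcm_features(avg).items():
        out[f"glcm_{name}_avg"] = value
    n_voxels = int(mask.sum())
    for key in OFFSETS:
        R = glrlm_matrix(levels, key, n_bins)
        for name, value in glrlm_features(R, n_voxels).items():
            out[f"glrlm_{name}_{key}"] = value
    return out
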