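"""Independent brute-force oracles for the surface metrics.

These recompute each metric from first principles — explicit boundary
enumeration and O(|S_a| * |S_b|) pairwise Euclidean distances — without
touching the library's KD-tree/erosion implementations beyond the shared
definition of the metrics themselves.
"""

import numpy as np


def boundary_indices(vox):
    """Foreground voxels with a 6-neighbor that is background or outside."""
    out = []
    shape = vox.shape
    for idx in np.argwhere(vox):
        i, j, k = idx
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                out.append((i, j, k))
                break
            if not vox[ni, nj, nk]:
                out.append((i, j, k))
                break
    return np.array(out, dtype=float).reshape(-1, 3)


def boundary_points_mm(mask):
    idx = boundary_indices(mask.voxels)
    return idx * np.array(mask.spacing) + np.array(mask.origin)


def pairwise_directed_distances(pts_a, pts_b):
    """min_b ||a - b|| for every a, by explicit pairwise distances."""
    diffs = pts_a[:, None, :] - pts_b[None, :, :]
    return np.sqrt((diffs**2).sum(axis=2)).min(axis=1)


def oracle_msd_hd95(mask_a, mask_b):
    pa, pb = boundary_points_mm(mask_a), boundary_points_mm(mask_b)
    d_ab = pairwise_directed_distances(pa, pb)
    d_ba = pairwise_directed_distances(pb, pa)
    msd = 0.5 * (d_ab.mean() + d_ba.mean())
    hd95 = max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))
    return float(msd), float(hd95)


def oracle_surface_dice(mask_a, mask_b, tau_mm):
    pa, pb = boundary_points_mm(mask_a), boundary_points_mm(mask_b)
    d_ab = pairwise_directed_distances(pa, pb)
    d_ba = pairwise_directed_distances(pb, pa)
    eps = 1e-9
    hits = int((d_ab <= tau_mm + eps).sum()) + int((d_ba <= tau_mm + eps).sum())
    return hits / (len(pa) + len(pb))


def boundary_indices_2d(sl):
    """4-connectivity in-plane boundary pixels of one 2D slice."""
    out = []
    shape = sl.shape
    for j, k in np.argwhere(sl):
        for dj, dk in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nj, nk = j + dj, k + dk
            if not (0 <= nj < shape[0] and 0 <= nk < shape[1]) or not sl[nj, nk]:
                out.append((j, k))
                break
    return out


def oracle_apl(ref, test, tau_mm):
    """Slice-wise added path length in mm by explicit pixel checks."""
    spacing = np.array(ref.spacing)
    pix = 0.5 * (spacing[1] + spacing[2])
    test_pts = boundary_points_mm(test)
    n_added = 0
    for i in range(ref.shape[0]):
        for j, k in boundary_indices_2d(ref.voxels[i]):
            if len(test_pts) == 0:
                n_added += 1
                continue
            p = np.array([i, j, k]) * spacing + np.array(ref.origin)
            d = np.sqrt(((test_pts - p) ** 2).sum(axis=1)).min()
            if d > tau_mm + 1e-9:
                n_added += 1
    return n_added * pix
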