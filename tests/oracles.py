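"""Independent brute-force oracles used to verify the fast implementations.

Everything here walks voxels/pairs/cells one by one in plain Python, kept
deliberately separate from the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def quantize_voxel(x: float, mu: float, sigma: float, ng: int) -> int:
    """Scalar clip-and-bin rule applied to one intensity."""
    if sigma == 0:
        return 1
    lo, hi = mu - 3 * sigma, mu + 3 * sigma
    x = min(max(x, lo), hi)
    level = 1 + math.floor((x - lo) / (6 * sigma) * ng)
    return min(level, ng)


def glcm_pairs(dense: np.ndarray, offset, ng: int) -> np.ndarray:
    """Symmetric co-occurrence counts by exhaustive double loop over voxels."""
    counts = np.zeros((ng, ng))
    shape = dense.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                a = dense[i, j, k]
                if a == 0:
                    continue
                ii, jj, kk = i + offset[0], j + offset[1], k + offset[2]
                if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                    continue
                b = dense[ii, jj, kk]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def haralick_naive(p: np.ndarray) -> dict[str, float]:
    """The 11 co-occurrence statistics by naive summation over all cells."""
    ng = p.shape[0]
    idx = range(1, ng + 1)
    mu_x = sum(i * p[i - 1, j - 1] for i in idx for j in idx)
    mu_y = sum(j * p[i - 1, j - 1] for i in idx for j in idx)
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * p[i - 1, j - 1] for i in idx for j in idx))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * p[i - 1, j - 1] for i in idx for j in idx))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in idx:
        for j in idx:
            p_sum[i + j] += p[i - 1, j - 1]
            p_diff[abs(i - j)] += p[i - 1, j - 1]
    out = {}
    out["AngScMom"] = sum(p[i - 1, j - 1] ** 2 for i in idx for j in idx)
    out["Contrast"] = sum((i - j) ** 2 * p[i - 1, j - 1] for i in idx for j in idx)
    if sd_x * sd_y > 0:
        out["Correlat"] = (
            sum(i * j * p[i - 1, j - 1] for i in idx for j in idx) - mu_x * mu_y
        ) / (sd_x * sd_y)
    else:
        out["Correlat"] = 0.0
    out["SumOfSqs"] = sum((i - mu_x) ** 2 * p[i - 1, j - 1] for i in idx for j in idx)
    out["InvDfMom"] = sum(
        p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx
    )
    sum_avg = sum(k * v for k, v in p_sum.items())
    out["SumAverg"] = sum_avg
    out["SumVarnc"] = sum((k - sum_avg) ** 2 * v for k, v in p_sum.items())
    out["SumEntrp"] = -sum(v * math.log(v) for v in p_sum.values() if v > 0)
    out["Entropy"] = -sum(
        p[i - 1, j - 1] * math.log(p[i - 1, j - 1])
        for i in idx
        for j in idx
        if p[i - 1, j - 1] > 0
    )
    diff_avg = sum(k * v for k, v in p_diff.items())
    out["DifVarnc"] = sum((k - diff_avg) ** 2 * v for k, v in p_diff.items())
    out["DifEntrp"] = -sum(v * math.log(v) for v in p_diff.values() if v > 0)
    return out


_DIRECTION_STEPS = {
    "Z": (0, 0, 1),
    "Horzl": (0, 1, 0),
    "Vertl": (1, 0, 0),
    "45dgr": (1, 1, 0),
    "135dr": (1, -1, 0),
}


def rlm_runs(dense: np.ndarray, direction: str) -> list[tuple[int, int]]:
    """(level, length) of every maximal run, by walking each lattice line
    voxel by voxel; non-VOI voxels (level 0) break runs."""
    step = _DIRECTION_STEPS[direction]
    shape = dense.shape
    # line starts: voxels with no predecessor along the step
    runs = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                pi, pj, pk = i - step[0], j - step[1], k - step[2]
                if 0 <= pi < shape[0] and 0 <= pj < shape[1] and 0 <= pk < shape[2]:
                    continue  # not a line start
                # walk the line
                ci, cj, ck = i, j, k
                current = 0
                length = 0
                while 0 <= ci < shape[0] and 0 <= cj < shape[1] and 0 <= ck < shape[2]:
                    v = dense[ci, cj, ck]
                    if v == current:
                        length += 1
                    else:
                        if current > 0:
                            runs.append((current, length))
                        current = v
                        length = 1
                    ci, cj, ck = ci + step[0], cj + step[1], ck + step[2]
                if current > 0:
                    runs.append((current, length))
    return runs


def rlm_stats_naive(runs: list[tuple[int, int]], n_voxels: int) -> dict[str, float]:
    nr = len(runs)
    levels = sorted({lv for lv, _ in runs})
    lengths = sorted({ln for _, ln in runs})
    per_level = {lv: sum(1 for l2, _ in runs if l2 == lv) for lv in levels}
    per_length = {ln: sum(1 for _, l2 in runs if l2 == ln) for ln in lengths}
    return {
        "GLevNonU": sum(v**2 for v in per_level.values()) / nr,
        "RLNonUni": sum(v**2 for v in per_length.values()) / nr,
        "ShrtREmp": sum(v / ln**2 for ln, v in per_length.items()) / nr,
        "LngREmph": sum(v * ln**2 for ln, v in per_length.items()) / nr,
        "Fraction": nr / n_voxels,
    }


def auc_concordance(scores, labels) -> float:
    """AUC as the exhaustive count of concordant pairs (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s1 in pos:
        for s0 in neg:
            if s1 > s0:
                total += 1.0
            elif s1 == s0:
                total += 0.5
    return total / (len(pos) * len(neg))


def gradient_magnitudes_naive(dense: np.ndarray, mask: np.ndarray) -> list[float]:
    """Central-difference gradient magnitude at 6-neighborhood-interior voxels."""
    out = []
    shape = dense.shape
    for i in range(1, shape[0] - 1):
        for j in range(1, shape[1] - 1):
            for k in range(1, shape[2] - 1):
                neigh = [
                    (i - 1, j, k), (i + 1, j, k),
                    (i, j - 1, k), (i, j + 1, k),
                    (i, j, k - 1), (i, j, k + 1),
                ]
                if not mask[i, j, k] or not all(mask[n] for n in neigh):
                    continue
                gx = (dense[i + 1, j, k] - dense[i - 1, j, k]) / 2
                gy = (dense[i, j + 1, k] - dense[i, j - 1, k]) / 2
                gz = (dense[i, j, k + 1] - dense[i, j, k - 1]) / 2
                out.append(math.sqrt(gx**2 + gy**2 + gz**2))
    return out
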