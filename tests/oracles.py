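"""Independent brute-force oracles for the texture matrices and clustering.

Everything here is written as literal, loop-based transcriptions of the
definitions, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def glcm_oracle(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-pixel-pair enumeration of the symmetrized 4-direction average GLCM."""
    rows, cols = levels.shape
    acc = np.zeros((n_levels, n_levels))
    for drow, dcol in GLCM_OFFSETS:
        counts = np.zeros((n_levels, n_levels))
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + drow, c + dcol
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                    counts[levels[r2, c2] - 1, levels[r, c] - 1] += 1
        acc += counts / counts.sum()
    return acc / len(GLCM_OFFSETS)


def glcm_features_oracle(p: np.ndarray) -> dict[str, float]:
    """Literal double-sum evaluation of ASM, correlation and contrast."""
    L = p.shape[0]
    asm = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    mu_i = sum((i + 1) * p[i, j] for i in range(L) for j in range(L))
    mu_j = sum((j + 1) * p[i, j] for i in range(L) for j in range(L))
    var_i = sum((i + 1 - mu_i) ** 2 * p[i, j] for i in range(L) for j in range(L))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    if var_i <= 0 or var_j <= 0:
        corr = 0.0
    else:
        cov = sum(
            (i + 1 - mu_i) * (j + 1 - mu_j) * p[i, j] for i in range(L) for j in range(L)
        )
        corr = cov / np.sqrt(var_i * var_j)
    return {"angular_second_moment": asm, "correlation": corr, "contrast_glcm": contrast}


def _scan_lines(levels: np.ndarray, direction: int) -> list[list[int]]:
    rows, cols = levels.shape
    if direction == 0:
        return [[levels[r, c] for c in range(cols)] for r in range(rows)]
    if direction == 90:
        return [[levels[r, c] for r in range(rows)] for c in range(cols)]
    lines = []
    if direction == 45:  # up-right
        starts = [(r, 0) for r in range(rows)] + [(rows - 1, c) for c in range(1, cols)]
        step = (-1, 1)
    else:  # 135, down-right
        starts = [(r, 0) for r in range(rows - 1, 0, -1)] + [(0, c) for c in range(cols)]
        step = (1, 1)
    for r, c in starts:
        line = []
        while 0 <= r < rows and 0 <= c < cols:
            line.append(levels[r, c])
            r += step[0]
            c += step[1]
        lines.append(line)
    return lines


def glrlm_oracle(levels: np.ndarray, n_levels: int, direction: int) -> np.ndarray:
    """Scan-line run counting; matrix (gray level i, run length j), 1-based."""
    max_len = max(levels.shape)
    r = np.zeros((n_levels, max_len))
    for line in _scan_lines(levels, direction):
        k = 0
        while k < len(line):
            j = k
            while j < len(line) and line[j] == line[k]:
                j += 1
            r[line[k] - 1, (j - k) - 1] += 1
            k = j
    return r


def glrlm_features_oracle(r: np.ndarray, n_pixels: int) -> dict[str, float]:
    """Literal-formula evaluation of the 11 run-length features."""
    L, J = r.shape
    nr = r.sum()
    out = dict.fromkeys(
        ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge"),
        0.0,
    )
    for i in range(1, L + 1):
        for j in range(1, J + 1):
            v = r[i - 1, j - 1]
            out["sre"] += v / j**2
            out["lre"] += v * j**2
            out["lgre"] += v / i**2
            out["hgre"] += v * i**2
            out["srlge"] += v / (i**2 * j**2)
            out["srhge"] += v * i**2 / j**2
            out["lrlge"] += v * j**2 / i**2
            out["lrhge"] += v * i**2 * j**2
    out["gln"] = sum(r[i].sum() ** 2 for i in range(L))
    out["rln"] = sum(r[:, j].sum() ** 2 for j in range(J))
    for key in out:
        out[key] /= nr
    out["rp"] = nr / n_pixels
    return out


def ngtdm_oracle(levels: np.ndarray, n_levels: int, d: int):
    """Per-pixel neighborhood enumeration: returns (s, counts, n)."""
    rows, cols = levels.shape
    s = np.zeros(n_levels)
    counts = np.zeros(n_levels, dtype=int)
    n = 0
    for r in range(d, rows - d):
        for c in range(d, cols - d):
            nbrs = [
                levels[r + dr, c + dc]
                for dr in range(-d, d + 1)
                for dc in range(-d, d + 1)
                if not (dr == 0 and dc == 0)
            ]
            tone = levels[r, c]
            s[tone - 1] += abs(tone - np.mean(nbrs))
            counts[tone - 1] += 1
            n += 1
    return s, counts, n


def ngtdm_contrast_oracle(s, counts, n) -> float:
    present = [i for i in range(len(counts)) if counts[i] > 0]
    ng = len(present)
    if ng < 2:
        return 0.0
    p = {i: counts[i] / n for i in present}
    spread = sum(
        p[i] * p[j] * ((i + 1) - (j + 1)) ** 2 for i in present for j in present
    )
    return spread / (ng * (ng - 1)) * sum(s) / n


def average_linkage_two_cut_oracle(x: np.ndarray) -> np.ndarray:
    """Naive agglomerative average-linkage replay, cut at two clusters.

    Cluster distance = mean pairwise Euclidean distance; at each step the
    closest pair of clusters merges, until two remain. Returns labels in
    {1, 2} with cluster 1 containing index 0.
    """
    n = x.shape[0]
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 2:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dd = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dd < best[0]:
                best = (dd, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    first = 0 if 0 in clusters[0] else 1
    labels[clusters[first]] = 1
    labels[clusters[1 - first]] = 2
    return labels
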