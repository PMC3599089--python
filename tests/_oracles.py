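"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain Python loops over the grid,
independent of the vectorised implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def sphere_offsets_bruteforce(radius: float, spacing: float) -> list[tuple[int, int, int]]:
    m = int(math.floor(radius / spacing))
    out = []
    for dx in range(-m, m + 1):
        for dy in range(-m, m + 1):
            for dz in range(-m, m + 1):
                if (dx * dx + dy * dy + dz * dz) * spacing * spacing <= radius * radius:
                    out.append((dx, dy, dz))
    return out


def solid_angle_bruteforce(occ: np.ndarray, voxel, radius: float, spacing: float) -> float:
    """Triple-loop voxel count of (V_in / V_sphere) * 4*pi."""
    i, j, k = voxel
    v_sphere = 0
    v_in = 0
    m = int(math.floor(radius / spacing))
    for dx in range(-m, m + 1):
        for dy in range(-m, m + 1):
            for dz in range(-m, m + 1):
                if (dx * dx + dy * dy + dz * dz) * spacing * spacing > radius * radius:
                    continue
                v_sphere += 1
                x, y, z = i + dx, j + dy, k + dz
                if 0 <= x < occ.shape[0] and 0 <= y < occ.shape[1] and 0 <= z < occ.shape[2]:
                    if occ[x, y, z]:
                        v_in += 1
    return (v_in / v_sphere) * 4.0 * math.pi


def surface_bruteforce(occ: np.ndarray) -> set[tuple[int, int, int]]:
    """O(N*6) neighbour scan; out-of-bounds counts as empty."""
    nx, ny, nz = occ.shape
    surf = set()
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not occ[i, j, k]:
                    continue
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    x, y, z = i + di, j + dj, k + dk
                    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz) or not occ[x, y, z]:
                        surf.add((i, j, k))
                        break
    return surf


_DIRS = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1)]


def direction_count_bruteforce(occ: np.ndarray, voxel) -> int:
    """Independent ray march: lines blocked by occupancy in both directions."""
    nx, ny, nz = occ.shape

    def hits(i, j, k, di, dj, dk):
        while True:
            i, j, k = i + di, j + dj, k + dk
            if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
                return False
            if occ[i, j, k]:
                return True

    i, j, k = voxel
    n = 0
    for di, dj, dk in _DIRS:
        if hits(i, j, k, di, dj, dk) and hits(i, j, k, -di, -dj, -dk):
            n += 1
    return n


def metrics_oracle(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Confusion metrics via scikit-learn on reconstructed label vectors."""
    from sklearn.metrics import accuracy_score, matthews_corrcoef, precision_score, recall_score

    y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
    y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "sensitivity": recall_score(y_true, y_pred, zero_division=0.0) if (tp + fn) else 0.0,
        "specificity": recall_score(y_true, y_pred, pos_label=0, zero_division=0.0)
        if (tn + fp)
        else 0.0,
        "ppv": precision_score(y_true, y_pred, zero_division=0.0) if (tp + fp) else 0.0,
    }
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = matthews_corrcoef(y_true, y_pred) if denom else 0.0
    return out


def random_blob_occupancy(rng: np.random.Generator, size: int, margin: int) -> np.ndarray:
    """Random union of balls confined to the grid interior (margin kept empty)."""
    occ = np.zeros((size, size, size), dtype=bool)
    lo, hi = margin, size - margin
    n_balls = rng.integers(1, 4)
    idx = np.indices(occ.shape)
    for _ in range(n_balls):
        c = rng.uniform(lo + 1, hi - 1, size=3)
        r = rng.uniform(1.5, (hi - lo) / 2)
        d2 = (idx[0] - c[0]) ** 2 + (idx[1] - c[1]) ** 2 + (idx[2] - c[2]) ** 2
        occ |= d2 <= r * r
    occ[:lo, :, :] = occ[hi:, :, :] = False
    occ[:, :lo, :] = occ[:, hi:, :] = False
    occ[:, :, :lo] = occ[:, :, hi:] = False
    return occ
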