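"""Independent brute-force oracles used to check the implementation.

Each oracle deliberately takes the slow, obvious route (exhaustive
lattice scans, explicit flood fill, closed-form statistics, a generic
QP solve of the SVM dual) so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

_OFFSETS = {
    6: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) == 1],
    18: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if 1 <= abs(dx) + abs(dy) + abs(dz) <= 2],
    26: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)],
}


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set]:
    """Connected components as sets of voxel tuples, via explicit flood fill."""
    offsets = _OFFSETS[connectivity]
    shape = binary.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= nb[a] < shape[a] for a in range(3)) and binary[nb] \
                        and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(comp)
    return comps


def ellipsoid_lattice_count(shape, center, semi) -> int:
    """Exhaustive triple-loop count of lattice points inside an ellipsoid."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                q = (((i - center[0]) / semi[0]) ** 2
                     + ((j - center[1]) / semi[1]) ** 2
                     + ((k - center[2]) / semi[2]) ** 2)
                if q <= 1.0:
                    count += 1
    return count


def sphere_lattice_points(grid, center_mm, radius_mm) -> set:
    """Exhaustive scan for lattice points within radius of a mm center."""
    pts = set()
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                xyz = grid.voxel_to_mm(np.array([i, j, k]))
                if np.sum((xyz - np.asarray(center_mm)) ** 2) <= radius_mm**2:
                    pts.add((i, j, k))
    return pts


def pooled_two_sample_t(healthy: np.ndarray, disease: np.ndarray) -> tuple[float, int]:
    """Textbook pooled two-sample t (healthy minus disease) and its df."""
    n1, n2 = len(healthy), len(disease)
    v1 = np.var(healthy, ddof=1) if n1 > 1 else 0.0
    v2 = np.var(disease, ddof=1) if n2 > 1 else 0.0
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (np.mean(healthy) - np.mean(disease)) / se if se > 0 else 0.0
    return float(t), df


def qp_linear_svm(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Solve the soft-margin SVM dual with a generic SLSQP QP solve."""
    n = len(y)
    yf = y.astype(float)
    Q = (yf[:, None] * yf[None, :]) * (X @ X.T)
    cons = [{"type": "eq", "fun": lambda a: a @ yf, "jac": lambda a: yf}]
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.full(n, 0.5 * min(C, 1.0)),
        jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = res.x
    w = (a * yf) @ X
    margin_sv = (a > 1e-6) & (a < C - 1e-6)
    sv = margin_sv if margin_sv.any() else a > 1e-6
    b = float(np.mean(yf[sv] - X[sv] @ w))
    return w, b


def gaussian_kernel_1d(sigma_vox: float, half_width: int) -> np.ndarray:
    """Direct evaluation of the sampled Gaussian, normalized to unit sum."""
    x = np.arange(-half_width, half_width + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return k / k.sum()
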