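"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: rigid alignment via
an exhaustive rotation-grid search with closed-form translation, Welch's
test from first-principles formulas, and plain 4x4 matrix arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def matmul_4x4(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Direct homogeneous matrix product."""
    return np.asarray(a, dtype=float) @ np.asarray(b, dtype=float)


def invert_closed_form(rotation: np.ndarray, translation: np.ndarray):
    """(R, t)^-1 = (R^T, -R^T t)."""
    rt = np.asarray(rotation).T
    return rt, -rt @ np.asarray(translation)


def _residual(rotvec, test_pts, ref_pts):
    r = Rotation.from_rotvec(rotvec).as_matrix()
    moved = test_pts @ r.T
    # optimal translation for a fixed rotation is the centroid difference
    t = ref_pts.mean(axis=0) - moved.mean(axis=0)
    return float(np.sum((moved + t - ref_pts) ** 2))


def brute_force_rigid_residual(
    test_pts: np.ndarray, ref_pts: np.ndarray, grid_step_deg: float = 20.0
) -> float:
    """Best rigid-fit residual via SO(3) grid search + local refinement.

    No SVD anywhere: rotations are enumerated over an Euler-angle grid,
    the translation is closed-form per rotation, and the best grid cell
    is polished with Nelder-Mead on the rotation vector.
    """
    test_pts = np.asarray(test_pts, dtype=float)
    ref_pts = np.asarray(ref_pts, dtype=float)
    step = np.deg2rad(grid_step_deg)
    best, best_rv = np.inf, np.zeros(3)
    alphas = np.arange(-np.pi, np.pi, step)
    betas = np.arange(-np.pi / 2, np.pi / 2 + 1e-9, step)
    for a in alphas:
        for b in betas:
            for c in alphas:
                rv = Rotation.from_euler("zyx", [a, b, c]).as_rotvec()
                r = _residual(rv, test_pts, ref_pts)
                if r < best:
                    best, best_rv = r, rv
    res = minimize(
        _residual,
        best_rv,
        args=(test_pts, ref_pts),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    return float(min(best, res.fun))


def welch_by_hand(a, b) -> tuple[float, float]:
    """Welch statistic and Satterthwaite df from the textbook formulas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    ma = a.sum() / na
    mb = b.sum() / nb
    va = ((a - ma) ** 2).sum() / (na - 1)
    vb = ((b - mb) ** 2).sum() / (nb - 1)
    t = (ma - mb) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return float(t), float(df)


def moments_list(mean: float, sd: float, n: int = 5) -> np.ndarray:
    """n values with exactly the given sample mean and sd (ddof=1)."""
    base = np.arange(n, dtype=float) - (n - 1) / 2.0
    base /= base.std(ddof=1)
    return mean + sd * base


def stability_by_hand(times, points, t_trig, stab_window, avg_window):
    """Windowed mean/stability recomputed with plain loops."""
    stab_pts = [
        p for t, p in zip(times, points) if t_trig - stab_window - 1e-12 <= t <= t_trig + 1e-12
    ]
    avg_pts = [
        p for t, p in zip(times, points) if t_trig - avg_window - 1e-12 <= t <= t_trig + 1e-12
    ]
    mean = np.mean(stab_pts, axis=0)
    stability = max(float(np.linalg.norm(np.asarray(p) - mean)) for p in stab_pts)
    return np.mean(avg_pts, axis=0), stability
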