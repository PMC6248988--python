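"""SVD-free brute-force rigid-fit oracle used by the acceptance report.

Rotations enumerated over an Euler-angle grid with closed-form
translation per rotation, then the best cell is refined with
Nelder-Mead on the rotation vector.  Kept independent of the package's
cross-covariance/SVD solver so the two routes can be compared.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def _residual(rotvec, test_pts, ref_pts):
    r = Rotation.from_rotvec(rotvec).as_matrix()
    moved = test_pts @ r.T
    t = ref_pts.mean(axis=0) - moved.mean(axis=0)
    return float(np.sum((moved + t - ref_pts) ** 2))


def brute_force_rigid_residual(test_pts, ref_pts, grid_step_deg: float = 20.0) -> float:
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
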