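"""Endpoint (pivot) calibration of a tracked stylus.

Given N rigid poses T_i recorded while the physical stylus tip stays at
one fixed location in space, the tip offset ``x_c`` in the device frame
is the vector minimizing the spread of the implied global tip positions

    x_g_i = R_i @ x_c + t_i

around their mean.  The estimator solves this with constrained nonlinear
optimization, initialized (and independently cross-checkable) by a
closed-form linear least-squares pivot solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import ConvergenceError, DegenerateCalibrationError
from .geometry import DEFAULT_ENDPOINT_BOUND_MM, EndpointOffset, RigidTransform

__all__ = [
    "CalibrationSet",
    "CalibrationResult",
    "calibrate_endpoint",
    "linear_pivot_oracle",
    "calibration_quality",
]

#: Smallest singular value of the stacked centered-rotation system below
#: which the tip offset is unidentifiable.
DIVERSITY_THRESHOLD = 1e-3


@dataclass
class CalibrationSet:
    """N >= 3 poses sharing one fixed physical tip location."""

    transforms: list[RigidTransform]

    def __post_init__(self):
        if len(self.transforms) < 3:
            raise DegenerateCalibrationError(
                f"need at least 3 calibration poses, got {len(self.transforms)}"
            )

    def __len__(self) -> int:
        return len(self.transforms)

    def rotations(self) -> np.ndarray:
        return np.array([t.rotation for t in self.transforms])

    def translations(self) -> np.ndarray:
        return np.array([t.translation for t in self.transforms])

    def diversity(self) -> float:
        """Smallest singular value of the stacked (R_i - mean R) system.

        Zero when all rotations are identical (pure translations cannot
        identify the tip); small when rotations share a single axis.
        """
        rots = self.rotations()
        centered = rots - rots.mean(axis=0)
        sv = np.linalg.svd(centered.reshape(-1, 3), compute_uv=False)
        return float(sv[-1])

    def is_degenerate(self, threshold: float = DIVERSITY_THRESHOLD) -> bool:
        return self.diversity() < threshold


@dataclass
class CalibrationResult:
    """Estimated endpoint offset plus quality metrics."""

    endpoint: EndpointOffset
    fixed_point: np.ndarray          # estimated shared global tip position (mm)
    max_deviation: float             # mm, max distance of any tip estimate from the mean
    residuals: np.ndarray            # per-sample |x_g_i - mean| (mm)
    objective: float                 # sum of squared residuals (mm^2)
    n_samples: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "endpoint_mm": [float(v) for v in self.endpoint.offset],
            "fixed_point_mm": [float(v) for v in self.fixed_point],
            "max_deviation_mm": float(self.max_deviation),
            "n_samples": int(self.n_samples),
        }


def _tip_positions(cal: CalibrationSet, offset: np.ndarray) -> np.ndarray:
    return np.einsum("nij,j->ni", cal.rotations(), offset) + cal.translations()


def spread_objective(cal: CalibrationSet, offset: np.ndarray) -> float:
    """Sum of squared distances of implied tip positions from their mean."""
    xg = _tip_positions(cal, np.asarray(offset, dtype=float))
    r = xg - xg.mean(axis=0)
    return float(np.sum(r * r))


def linear_pivot_oracle(
    cal: CalibrationSet, diversity_threshold: float = DIVERSITY_THRESHOLD
) -> tuple[EndpointOffset, np.ndarray]:
    """Closed-form pivot solution from the stacked linear system.

    Solves ``R_i @ x_c - p = -t_i`` for the six unknowns (x_c, p) in
    least squares.  On noiseless input this equals the spread minimizer;
    on noisy input it serves as the optimizer's initialization and as an
    independent cross-check.
    """
    if cal.is_degenerate(diversity_threshold):
        raise DegenerateCalibrationError(
            "calibration poses are rank-deficient: rotations span "
            f"insufficient diversity (smallest singular value {cal.diversity():.3g} "
            f"< {diversity_threshold:.3g}); rotate the device about at least two "
            "distinct axes through the tip"
        )
    rots, trans = cal.rotations(), cal.translations()
    n = len(cal)
    a = np.zeros((3 * n, 6))
    a[:, :3] = rots.reshape(-1, 3)
    a[:, 3:] = -np.tile(np.eye(3), (n, 1))
    b = -trans.reshape(-1)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 6:
        raise DegenerateCalibrationError(
            f"stacked pivot system is rank deficient (rank {rank} < 6)"
        )
    offset, fixed_point = sol[:3], sol[3:]
    bound = max(DEFAULT_ENDPOINT_BOUND_MM, float(np.linalg.norm(offset)) + 1.0)
    return EndpointOffset(offset, bound_mm=bound), fixed_point


def calibration_quality(cal: CalibrationSet, endpoint: EndpointOffset) -> float:
    """Maximum deviation (mm) of any implied tip position from the mean.

    Reported as an unsquared distance so the number is directly in mm.
    """
    xg = _tip_positions(cal, endpoint.offset)
    dev = np.linalg.norm(xg - xg.mean(axis=0), axis=1)
    return float(dev.max())


def calibrate_endpoint(
    cal: CalibrationSet,
    bound_mm: float = DEFAULT_ENDPOINT_BOUND_MM,
    tol: float = 1e-9,
    max_iter: int = 500,
    diversity_threshold: float = DIVERSITY_THRESHOLD,
    allow_degenerate: bool = False,
) -> CalibrationResult:
    """Estimate the endpoint offset by constrained spread minimization.

    Parameters
    ----------
    cal
        Poses sharing one fixed tip location, N >= 3.
    bound_mm
        Norm bound on the offset (physical stylus stubs are centimeters).
    tol
        Convergence tolerance on objective change.
    allow_degenerate
        Skip the rotational-diversity check (the result is then
        unidentifiable along the deficient direction).
    """
    if not allow_degenerate and cal.is_degenerate(diversity_threshold):
        raise DegenerateCalibrationError(
            "calibration poses are degenerate (smallest singular value "
            f"{cal.diversity():.3g} < {diversity_threshold:.3g}); the endpoint is "
            "unidentifiable along the rotation-deficient direction"
        )

    rots, trans = cal.rotations(), cal.translations()
    rc = rots - rots.mean(axis=0)          # centered rotations
    tc = trans - trans.mean(axis=0)        # centered translations

    def objective(x):
        r = np.einsum("nij,j->ni", rc, x) + tc
        return float(np.sum(r * r))

    def gradient(x):
        r = np.einsum("nij,j->ni", rc, x) + tc
        return 2.0 * np.einsum("nij,ni->j", rc, r)

    if allow_degenerate:
        x0 = np.zeros(3)
    else:
        oracle_offset, _ = linear_pivot_oracle(cal, diversity_threshold)
        x0 = oracle_offset.offset.copy()
    norm0 = float(np.linalg.norm(x0))
    if norm0 > bound_mm:
        x0 = x0 * (bound_mm / norm0)

    res = minimize(
        objective,
        x0,
        jac=gradient,
        method="SLSQP",
        constraints=[
            {
                "type": "ineq",
                "fun": lambda x: bound_mm**2 - float(x @ x),
                "jac": lambda x: -2.0 * x,
            }
        ],
        options={"ftol": tol, "maxiter": max_iter},
    )
    if not res.success and res.fun > objective(x0) + tol:
        raise ConvergenceError(
            f"endpoint optimizer failed: {res.message}", objective=float(res.fun)
        )
    # Keep whichever of {optimizer result, initialization} is better; the
    # optimizer must never degrade a feasible start.
    x_best = res.x if res.fun <= objective(x0) else x0

    endpoint = EndpointOffset(x_best, bound_mm=bound_mm * (1 + 1e-12))
    xg = _tip_positions(cal, x_best)
    mean = xg.mean(axis=0)
    residuals = np.linalg.norm(xg - mean, axis=1)
    return CalibrationResult(
        endpoint=endpoint,
        fixed_point=mean,
        max_deviation=float(residuals.max()),
        residuals=residuals,
        objective=float(np.sum(residuals**2)),
        n_samples=len(cal),
    )
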