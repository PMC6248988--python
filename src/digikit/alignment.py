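"""Rigid alignment of digitization datasets and localization-error statistics.

One dataset is aligned to a reference with a single rigid transform
(rotation + translation, no scaling) fit in least squares over
label-matched point pairs — either the anatomical fiducials only or the
measured electrodes.  Localization error is then the per-electrode
Euclidean distance to the reference, aggregated as RMSE, and conditions
are compared with Welch's two-tailed t-test (Satterthwaite degrees of
freedom, no multiplicity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .errors import DegeneracyError, UnknownLabelError
from .geometry import RigidTransform
from .session import DigitizationSession

__all__ = [
    "CorrespondenceSet",
    "AlignmentResult",
    "GroupComparison",
    "rigid_align",
    "evaluate_dataset",
    "reject_electrodes",
    "welch_ttest",
    "reference_selection",
]

#: Second singular value of the centered pair cloud below this (relative
#: to the largest) means the pairs are essentially collinear.
_COLLINEAR_RTOL = 1e-8


@dataclass
class CorrespondenceSet:
    """Label-matched (test, reference) point pairs."""

    labels: list[str]
    test_points: np.ndarray      # (N, 3) mm
    ref_points: np.ndarray       # (N, 3) mm
    mode: str = "by-electrodes"

    def __post_init__(self):
        self.test_points = np.asarray(self.test_points, dtype=float).reshape(-1, 3)
        self.ref_points = np.asarray(self.ref_points, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.test_points) or len(self.labels) != len(
            self.ref_points
        ):
            raise ValueError("labels/points length mismatch")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class AlignmentResult:
    transform: RigidTransform
    per_label_error: dict[str, float]
    rmse: float
    max_error: float
    n_used: int
    mode: str = "by-electrodes"

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "transform": [list(map(float, row)) for row in self.transform.as_matrix()],
            "per_label_error_mm": {k: float(v) for k, v in self.per_label_error.items()},
            "rmse_mm": float(self.rmse),
            "max_error_mm": float(self.max_error),
            "n_used": int(self.n_used),
        }


def _check_nondegenerate(points: np.ndarray) -> None:
    if len(points) < 3:
        raise DegeneracyError(
            f"need at least 3 point pairs for a unique rigid alignment, got {len(points)}"
        )
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] <= 0 or sv[1] / sv[0] < _COLLINEAR_RTOL:
        raise DegeneracyError("alignment points are collinear or coincident")


def rigid_align(pairs: CorrespondenceSet) -> RigidTransform:
    """Least-squares rigid transform T minimizing sum |T(test_i) - ref_i|^2.

    Standard cross-covariance/SVD (Kabsch) solution; a reflection-only
    optimum is handled by flipping the smallest singular direction so
    the returned rotation always has determinant +1.
    """
    _check_nondegenerate(pairs.test_points)
    _check_nondegenerate(pairs.ref_points)
    tc = pairs.test_points.mean(axis=0)
    rc = pairs.ref_points.mean(axis=0)
    h = (pairs.test_points - tc).T @ (pairs.ref_points - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ tc
    return RigidTransform(rot, trans)


def alignment_residual(pairs: CorrespondenceSet, transform: RigidTransform) -> float:
    """Sum of squared distances after applying `transform` to the test points."""
    moved = transform.apply(pairs.test_points)
    return float(np.sum((moved - pairs.ref_points) ** 2))


def _shared_electrodes(
    test: DigitizationSession, ref: DigitizationSession
) -> tuple[list[str], np.ndarray, np.ndarray]:
    tpts = test.usable_electrodes()
    rpts = ref.usable_electrodes()
    labels = [l for l in test.montage.labels if l in tpts and l in rpts]
    if not labels:
        raise DegeneracyError("no shared non-rejected electrodes between sessions")
    return (
        labels,
        np.array([tpts[l] for l in labels]),
        np.array([rpts[l] for l in labels]),
    )


def evaluate_dataset(
    test: DigitizationSession, ref: DigitizationSession, mode: str = "electrodes"
) -> AlignmentResult:
    """Align `test` to `ref` and report per-electrode localization errors.

    `mode` selects the alignment points: aggregated fiducials or the
    shared non-rejected electrodes.  Errors are always computed over the
    shared non-rejected electrodes, whichever mode aligned the sets.
    """
    labels, tpts, rpts = _shared_electrodes(test, ref)
    if mode in ("electrodes", "by-electrodes"):
        pairs = CorrespondenceSet(labels, tpts, rpts, mode="by-electrodes")
    elif mode in ("fiducials", "by-fiducials"):
        tf = test.fiducial_positions()
        rf = ref.fiducial_positions()
        shared = [n for n in test.fiducials.names if n in tf and n in rf]
        if len(shared) < 3:
            raise DegeneracyError(
                f"by-fiducials alignment needs >= 3 shared fiducials, got {len(shared)}"
            )
        pairs = CorrespondenceSet(
            shared,
            np.array([tf[n] for n in shared]),
            np.array([rf[n] for n in shared]),
            mode="by-fiducials",
        )
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    transform = rigid_align(pairs)
    moved = transform.apply(tpts)
    errors = np.linalg.norm(moved - rpts, axis=1)
    return AlignmentResult(
        transform=transform,
        per_label_error=dict(zip(labels, map(float, errors))),
        rmse=float(np.sqrt(np.mean(errors**2))),
        max_error=float(errors.max()),
        n_used=len(labels),
        mode=pairs.mode,
    )


def reject_electrodes(session: DigitizationSession, labels) -> DigitizationSession:
    """Flag electrodes as rejected (excluded from alignment and errors)."""
    for label in labels:
        if label not in session.electrodes:
            raise UnknownLabelError(
                f"cannot reject {label!r}: not a measured electrode"
            )
        session.electrodes[label].rejected = True
    return session


@dataclass
class GroupComparison:
    """Welch's two-tailed t-test between two RMSE samples."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = field(default=False)

    def to_dict(self) -> dict:
        return {
            "t": float(self.t),
            "df": float(self.df),
            "p": float(self.p),
            "mean_a": float(self.mean_a),
            "mean_b": float(self.mean_b),
            "n_a": int(self.n_a),
            "n_b": int(self.n_b),
            "degenerate": bool(self.degenerate),
        }


def welch_ttest(a, b) -> GroupComparison:
    """Welch's unequal-variance t-test, two-tailed, Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite observations")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / na, vb / nb
    denom = sa + sb
    if denom == 0.0:
        # zero variance in both groups: identical means by convention p=1
        t = 0.0 if ma == mb else np.inf * np.sign(ma - mb)
        p = 1.0 if ma == mb else 0.0
        return GroupComparison(
            t=float(t), df=float(na + nb - 2), p=p,
            mean_a=float(ma), mean_b=float(mb), n_a=na, n_b=nb, degenerate=True,
        )
    t = (ma - mb) / np.sqrt(denom)
    df = denom**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return GroupComparison(
        t=float(t), df=float(df), p=p,
        mean_a=float(ma), mean_b=float(mb), n_a=na, n_b=nb,
    )


def reference_selection(candidates: list[DigitizationSession]) -> int:
    """Index of the reference dataset among repeated candidates.

    The first candidate is the default; if any later candidate rejected
    strictly fewer electrodes than the first, the (earliest) candidate
    with the fewest rejections is used instead.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    counts = [s.n_rejected() for s in candidates]
    if min(counts[1:], default=counts[0]) < counts[0]:
        return int(np.argmin(counts))
    return 0
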