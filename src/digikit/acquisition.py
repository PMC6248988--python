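"""From raw pose streams to validated measurements.

Raw consumer-VR tracking carries high-frequency jitter plus transient
error that persists for a while after the controller stops moving.  Each
triggered measurement is therefore (a) averaged over a trailing window
(default 0.5 s) and (b) gated on stability: every endpoint sample in a
longer trailing window (default 1.0 s) must stay within a threshold
(default 1 mm) of the window mean.

When head trackers are configured, the endpoint is re-expressed in
tracker-relative coordinates sample by sample *before* averaging — that
is the frame in which a point fixed on a moving head is stationary —
then mapped back to global coordinates through the tracker poses at
session start, so measurements taken at different head poses live in a
single head-fixed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientDataError,
    MissingTrackerError,
)
from .geometry import EndpointOffset, RigidTransform
from .posestream import TIME_MATCH_TOL_S, DeviceTrack, PoseStream, TriggerEvent

__all__ = [
    "MeasurementSample",
    "TrackerConfig",
    "endpoint_timeseries",
    "sample_measurement",
    "compensate_head",
    "detect_tracker_mismatch",
    "MismatchReport",
]

AVG_WINDOW_S = 0.5
STAB_WINDOW_S = 1.0
STAB_THRESHOLD_MM = 1.0
MISMATCH_THRESHOLD_MM = 3.0
MISMATCH_PROBE_MM = 100.0
MIN_WINDOW_SAMPLES = 3


@dataclass(frozen=True)
class TrackerConfig:
    """One or two head-tracker device ids plus the slip-warning threshold."""

    tracker_ids: tuple[str, ...]
    mismatch_threshold_mm: float = MISMATCH_THRESHOLD_MM

    def __post_init__(self):
        ids = tuple(self.tracker_ids)
        if not 1 <= len(ids) <= 2:
            raise ValueError("expected 1 or 2 tracker ids")
        if len(set(ids)) != len(ids):
            raise ValueError("tracker ids must be distinct")
        object.__setattr__(self, "tracker_ids", ids)


@dataclass
class MeasurementSample:
    """One accepted (or rejected-as-unstable) measurement."""

    label: str
    role: str                         # fiducial | electrode | headshape
    position: np.ndarray              # mm, in `frame`
    frame: str                        # "global" or "head-reference(id1,id2)"
    valid: bool
    stability_mm: float
    window_n: int
    time: float = 0.0


def endpoint_timeseries(
    stream: PoseStream, device: str, endpoint: EndpointOffset
) -> tuple[np.ndarray, np.ndarray]:
    """Global endpoint position per pose sample of `device`.

    Returns ``(times (N,), points (N,3))`` with stream order preserved.
    """
    track = stream.track(device)
    pts = (
        np.einsum("nij,j->ni", track.rotations, endpoint.offset) + track.translations
    )
    return track.times.copy(), pts


def _window_slice(times: np.ndarray, t_end: float, width: float) -> slice:
    lo = int(np.searchsorted(times, t_end - width - 1e-12))
    hi = int(np.searchsorted(times, t_end + 1e-12))
    return slice(lo, hi)


def sample_measurement(
    times: np.ndarray,
    points: np.ndarray,
    trigger: TriggerEvent | float,
    label: str = "",
    role: str = "electrode",
    frame: str = "global",
    avg_window: float = AVG_WINDOW_S,
    stab_window: float = STAB_WINDOW_S,
    stab_thresh: float = STAB_THRESHOLD_MM,
) -> MeasurementSample:
    """Average + stability-gate one trigger against an endpoint time series.

    Both windows trail the trigger time.  The reported position is the
    mean over the trailing `avg_window`; stability is the maximum
    distance of any sample in the trailing `stab_window` from that
    window's own mean, and the measurement is valid iff it does not
    exceed `stab_thresh`.
    """
    if avg_window > stab_window:
        raise ValueError("avg_window must not exceed stab_window")
    t_trig = trigger.time if isinstance(trigger, TriggerEvent) else float(trigger)
    times = np.asarray(times, dtype=float)
    points = np.asarray(points, dtype=float)

    stab = _window_slice(times, t_trig, stab_window)
    avg = _window_slice(times, t_trig, avg_window)
    if (stab.stop - stab.start) < MIN_WINDOW_SAMPLES or (
        avg.stop - avg.start
    ) < MIN_WINDOW_SAMPLES:
        raise InsufficientDataError(
            f"fewer than {MIN_WINDOW_SAMPLES} samples in measurement window "
            f"ending at t={t_trig:.3f}s"
        )
    stab_pts = points[stab]
    stab_mean = stab_pts.mean(axis=0)
    stability = float(np.linalg.norm(stab_pts - stab_mean, axis=1).max())
    position = points[avg].mean(axis=0)
    return MeasurementSample(
        label=label,
        role=role,
        position=position,
        frame=frame,
        valid=stability <= stab_thresh,
        stability_mm=stability,
        window_n=int(avg.stop - avg.start),
        time=t_trig,
    )


def compensate_head(
    point_global: np.ndarray,
    tracker_poses: dict[str, RigidTransform],
    reference_poses: dict[str, RigidTransform],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Re-express a global point per head tracker and combine.

    ``per_tracker[k]`` is the point in tracker ``k``'s local frame.  The
    combined estimate maps each tracker-relative coordinate back through
    that tracker's *session-reference* pose (its pose at session start)
    and averages — i.e. the head-fixed point as it would appear in global
    coordinates with the head at its reference pose.
    """
    if not tracker_poses:
        raise MissingTrackerError("no tracker poses supplied")
    p = np.asarray(point_global, dtype=float)
    per_tracker: dict[str, np.ndarray] = {}
    mapped = []
    for tid, pose in tracker_poses.items():
        local = pose.inverse().apply(p)
        per_tracker[tid] = local
        if tid not in reference_poses:
            raise MissingTrackerError(f"no reference pose for tracker {tid!r}")
        mapped.append(reference_poses[tid].apply(local))
    return per_tracker, np.mean(mapped, axis=0)


@dataclass
class MismatchReport:
    """Result of comparing the relative transform of two head trackers over time."""

    applicable: bool
    mismatch: bool = False
    first_time: float | None = None
    magnitude_mm: float = 0.0          # at first exceedance
    max_magnitude_mm: float = 0.0
    threshold_mm: float = MISMATCH_THRESHOLD_MM
    times: np.ndarray | None = None
    magnitudes: np.ndarray | None = None


# probe points: +/-100 mm along each axis, a ~head-radius lever arm
_PROBES = np.vstack([np.eye(3), -np.eye(3)]) * MISMATCH_PROBE_MM


def detect_tracker_mismatch(
    stream: PoseStream,
    config: TrackerConfig,
    threshold_mm: float | None = None,
) -> MismatchReport:
    """Detect one tracker slipping on the head.

    Two trackers rigidly mounted on one head have a constant relative
    transform ``inv(T1) @ T2``.  The mismatch magnitude at each time is
    the largest displacement of a 100-mm probe point under the change of
    that relative transform since session start.  Single-tracker
    sessions yield a not-applicable report, not an error.
    """
    threshold = config.mismatch_threshold_mm if threshold_mm is None else threshold_mm
    if len(config.tracker_ids) < 2:
        return MismatchReport(applicable=False, threshold_mm=threshold)
    id1, id2 = config.tracker_ids
    tr1, tr2 = stream.track(id1), stream.track(id2)

    # pair tracker-2 samples to nearest tracker-1 samples
    idx = np.clip(np.searchsorted(tr1.times, tr2.times), 1, max(len(tr1) - 1, 1))
    left = tr1.times[idx - 1]
    right = tr1.times[np.minimum(idx, len(tr1) - 1)]
    use_left = np.abs(tr2.times - left) <= np.abs(tr2.times - right)
    j = np.where(use_left, idx - 1, np.minimum(idx, len(tr1) - 1))
    ok = np.abs(tr1.times[j] - tr2.times) <= TIME_MATCH_TOL_S
    if not ok.any():
        raise MissingTrackerError("tracker streams never overlap in time")

    t2_times = tr2.times[ok]
    r1, t1 = tr1.rotations[j[ok]], tr1.translations[j[ok]]
    r2, t2 = tr2.rotations[ok], tr2.translations[ok]
    # rel = inv(T1) @ T2
    rel_r = np.einsum("nji,njk->nik", r1, r2)
    rel_t = np.einsum("nji,nj->ni", r1, t2 - t1)

    # delta(t) = rel(t) @ inv(rel(t0)); probe displacement |delta q - q|
    r0, t0 = rel_r[0], rel_t[0]
    inv_r0, inv_t0 = r0.T, -r0.T @ t0
    d_r = np.einsum("nij,jk->nik", rel_r, inv_r0)
    d_t = np.einsum("nij,j->ni", rel_r, inv_t0) + rel_t
    moved = np.einsum("nij,pj->npi", d_r, _PROBES) + d_t[:, None, :]
    mags = np.linalg.norm(moved - _PROBES[None, :, :], axis=2).max(axis=1)

    exceed = np.nonzero(mags > threshold)[0]
    report = MismatchReport(
        applicable=True,
        threshold_mm=threshold,
        times=t2_times,
        magnitudes=mags,
        max_magnitude_mm=float(mags.max()),
    )
    if exceed.size:
        report.mismatch = True
        report.first_time = float(t2_times[exceed[0]])
        report.magnitude_mm = float(mags[exceed[0]])
    return report
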