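"""Replay-mode digitization: pose stream + montage -> session.

Triggers are consumed in order against a measurement plan (fiducials
first, then electrodes in montage order); an unstable measurement leaves
its target pending so the following trigger retries it, mirroring the
re-measure-on-invalid interaction of a live session.  Triggers beyond
the plan become free head-shape points.
"""

from __future__ import annotations

import numpy as np

from .acquisition import (
    AVG_WINDOW_S,
    STAB_THRESHOLD_MM,
    STAB_WINDOW_S,
    endpoint_timeseries,
    sample_measurement,
)
from .errors import InsufficientDataError, MissingTrackerError
from .geometry import EndpointOffset
from .montage import DEFAULT_FIDUCIAL_NAMES, Montage
from .posestream import TIME_MATCH_TOL_S, PoseStream
from .session import DigitizationSession, DigitizedPoint

__all__ = ["compensated_endpoint_timeseries", "digitize_stream"]


def _pair_indices(src_times: np.ndarray, dst_times: np.ndarray) -> np.ndarray:
    """For each src time, index of nearest dst sample; -1 if > 50 ms away."""
    idx = np.searchsorted(dst_times, src_times)
    idx = np.clip(idx, 1, max(len(dst_times) - 1, 1))
    left = idx - 1
    right = np.minimum(idx, len(dst_times) - 1)
    use_left = np.abs(src_times - dst_times[left]) <= np.abs(
        src_times - dst_times[right]
    )
    j = np.where(use_left, left, right)
    j[np.abs(dst_times[j] - src_times) > TIME_MATCH_TOL_S] = -1
    return j


def compensated_endpoint_timeseries(
    stream: PoseStream,
    controller: str,
    endpoint: EndpointOffset,
    tracker_ids: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint positions re-expressed in the head-reference frame.

    Each global endpoint sample is converted to tracker-relative
    coordinates (per tracker, nearest pose sample within 50 ms), mapped
    back through that tracker's session-start pose, and averaged across
    trackers.  Returns (times, points); samples missing any tracker pose
    are dropped.
    """
    times, pts = endpoint_timeseries(stream, controller, endpoint)
    keep = np.ones(len(times), dtype=bool)
    mapped_sum = np.zeros_like(pts)
    for tid in tracker_ids:
        track = stream.track(tid)
        if len(track) == 0:
            raise MissingTrackerError(f"tracker {tid!r} has no samples")
        j = _pair_indices(times, track.times)
        keep &= j >= 0
        jj = np.maximum(j, 0)
        rot = track.rotations[jj]
        trans = track.translations[jj]
        local = np.einsum("nji,nj->ni", rot, pts - trans)
        ref_r, ref_t = track.rotations[0], track.translations[0]
        mapped_sum += local @ ref_r.T + ref_t
    if not keep.any():
        raise MissingTrackerError("no controller sample has tracker poses within 50 ms")
    return times[keep], mapped_sum[keep] / max(len(tracker_ids), 1)


def build_plan(
    montage: Montage,
    fiducial_names: tuple[str, ...] = DEFAULT_FIDUCIAL_NAMES,
    fiducial_repeats: int = 1,
    headshape_refiducials: int = 0,
) -> list[tuple[str, str]]:
    """Ordered (label, role) measurement plan for a whole-head run."""
    plan = [(n, "fiducial") for n in fiducial_names for _ in range(fiducial_repeats)]
    plan += [(l, "electrode") for l in montage.labels]
    plan += [
        (n, "refiducial") for _ in range(headshape_refiducials) for n in fiducial_names
    ]
    return plan


def digitize_stream(
    stream: PoseStream,
    controller: str,
    endpoint: EndpointOffset,
    montage: Montage,
    tracker_ids: tuple[str, ...] = (),
    fiducial_names: tuple[str, ...] = DEFAULT_FIDUCIAL_NAMES,
    fiducial_repeats: int = 1,
    headshape_refiducials: int = 0,
    avg_window: float = AVG_WINDOW_S,
    stab_window: float = STAB_WINDOW_S,
    stab_thresh: float = STAB_THRESHOLD_MM,
    keep_invalid: bool = False,
) -> DigitizationSession:
    """Digitize a replayed stream into a session.

    With `keep_invalid` false (default), an unstable trigger does not
    consume its target; the next trigger re-attempts the same label.
    """
    if tracker_ids:
        times, pts = compensated_endpoint_timeseries(
            stream, controller, endpoint, tracker_ids
        )
        frame = "head-reference(" + ",".join(tracker_ids) + ")"
    else:
        times, pts = endpoint_timeseries(stream, controller, endpoint)
        frame = "global"

    session = DigitizationSession(montage=montage, tracker_ids=tuple(tracker_ids))
    session.fiducials.names = tuple(fiducial_names)
    session.provenance = {
        "system": "digikit-replay",
        "controller": controller,
        "endpoint_mm": [float(v) for v in endpoint.offset],
        "avg_window_s": avg_window,
        "stab_window_s": stab_window,
        "stab_threshold_mm": stab_thresh,
        "frame": frame,
    }

    plan = build_plan(montage, tuple(fiducial_names), fiducial_repeats, headshape_refiducials)
    cursor = 0
    n_headshape = 0
    for trig in stream.triggers:
        if trig.device != controller:
            continue
        if cursor < len(plan):
            label, role = plan[cursor]
        else:
            label, role = f"hs{n_headshape + 1}", "headshape"
        try:
            meas = sample_measurement(
                times,
                pts,
                trig,
                label=label,
                role="headshape" if role == "refiducial" else role,
                frame=frame,
                avg_window=avg_window,
                stab_window=stab_window,
                stab_thresh=stab_thresh,
            )
        except InsufficientDataError:
            session.warnings.append(
                f"trigger at t={trig.time:.3f}s skipped: too few samples in window"
            )
            continue
        if not meas.valid and not keep_invalid:
            session.warnings.append(
                f"measurement of {label!r} at t={trig.time:.3f}s invalid "
                f"(stability {meas.stability_mm:.2f} mm); target left pending"
            )
            continue
        point = DigitizedPoint(
            label=label,
            role=meas.role,
            position=meas.position,
            frame=frame,
            valid=meas.valid,
            stability_mm=meas.stability_mm,
            window_n=meas.window_n,
            time=meas.time,
        )
        if role == "fiducial":
            session.add_fiducial(label, meas.position)
        elif role == "electrode":
            session.add_electrode(point)
        elif role == "refiducial":
            session.add_headshape_refiducial(label, meas.position)
        else:
            session.add_headshape(point)
            n_headshape += 1
        if cursor < len(plan):
            cursor += 1
    return session
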