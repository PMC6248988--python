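"""Timestamped 6-DOF pose streams and their JSON-lines serialization.

One record per line.  Pose sample::

    {"t": 1.234, "device": "controller", "T": [16 floats, row-major 4x4]}

Trigger event::

    {"t": 1.234, "device": "controller", "event": "trigger"}

The bottom row of every ``T`` must be exactly ``0,0,0,1``.  Floats are
written with Python's shortest round-trip repr, which preserves all 17
significant digits of a double, so write-then-read is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, UnknownDeviceError
from .geometry import RigidTransform, nearest_rotation

__all__ = ["DeviceTrack", "TriggerEvent", "PoseStream", "read_pose_stream", "write_pose_stream"]

#: Max time distance for nearest-sample lookup across devices (seconds).
TIME_MATCH_TOL_S = 0.05

#: Per-sample rotation defect beyond which a stream is rejected outright.
_STREAM_REPAIR_TOL = 1e-6


@dataclass(frozen=True)
class TriggerEvent:
    """Button press marking one intended measurement."""

    time: float
    device: str


@dataclass
class DeviceTrack:
    """Dense pose samples of one device: times (N,), rotations (N,3,3), translations (N,3)."""

    times: np.ndarray
    rotations: np.ndarray
    translations: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        n = self.times.shape[0]
        if self.rotations.shape != (n, 3, 3) or self.translations.shape != (n, 3):
            raise ValueError("inconsistent track array shapes")

    def __len__(self) -> int:
        return int(self.times.shape[0])

    def validate_rigidity(self) -> None:
        """Check every rotation is orthonormal; repair tiny defects in place."""
        rtr = np.einsum("nij,nik->njk", self.rotations, self.rotations)
        defect = np.abs(rtr - np.eye(3)).max(axis=(1, 2))
        bad = defect > 1e-9
        if not bad.any():
            return
        worst = float(defect.max())
        if worst > _STREAM_REPAIR_TOL:
            raise FormatError(f"non-rigid pose in stream (defect {worst:.3g})")
        for i in np.nonzero(bad)[0]:
            self.rotations[i] = nearest_rotation(self.rotations[i])

    def nearest_index(self, t: float, tol_s: float = TIME_MATCH_TOL_S) -> int:
        """Index of the sample nearest in time to `t`, or -1 if none within tol."""
        i = int(np.searchsorted(self.times, t))
        best, best_dt = -1, tol_s
        for j in (i - 1, i):
            if 0 <= j < len(self.times):
                dt = abs(float(self.times[j]) - t)
                if dt <= best_dt:
                    best, best_dt = j, dt
        return best

    def pose_at(self, t: float, tol_s: float = TIME_MATCH_TOL_S) -> RigidTransform | None:
        i = self.nearest_index(t, tol_s)
        if i < 0:
            return None
        return RigidTransform(self.rotations[i], self.translations[i])


@dataclass
class PoseStream:
    """Multi-device pose stream plus embedded trigger events."""

    tracks: dict[str, DeviceTrack] = field(default_factory=dict)
    triggers: list[TriggerEvent] = field(default_factory=list)

    def devices(self) -> list[str]:
        return list(self.tracks)

    def track(self, device: str) -> DeviceTrack:
        try:
            return self.tracks[device]
        except KeyError:
            raise UnknownDeviceError(
                f"device {device!r} not in stream (have {sorted(self.tracks)})"
            ) from None

    @property
    def span(self) -> tuple[float, float]:
        starts = [float(tr.times[0]) for tr in self.tracks.values() if len(tr)]
        ends = [float(tr.times[-1]) for tr in self.tracks.values() if len(tr)]
        if not starts:
            return (0.0, 0.0)
        return (min(starts), max(ends))


def read_pose_stream(path) -> PoseStream:
    """Parse a JSONL pose-stream file; malformed lines report their number."""
    per_device: dict[str, list[tuple[float, list[float]]]] = {}
    triggers: list[TriggerEvent] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"invalid JSON: {exc.msg}", path, lineno) from exc
            if not isinstance(rec, dict) or "t" not in rec or "device" not in rec:
                raise FormatError("record needs 't' and 'device' fields", path, lineno)
            if rec.get("event") == "trigger":
                triggers.append(TriggerEvent(float(rec["t"]), str(rec["device"])))
                continue
            tmat = rec.get("T")
            if not isinstance(tmat, list) or len(tmat) != 16:
                raise FormatError("'T' must be a list of 16 floats", path, lineno)
            if tmat[12:16] != [0.0, 0.0, 0.0, 1.0]:
                raise FormatError(
                    f"bottom row must be 0,0,0,1; got {tmat[12:16]}", path, lineno
                )
            per_device.setdefault(str(rec["device"]), []).append((float(rec["t"]), tmat))

    tracks: dict[str, DeviceTrack] = {}
    for device, rows in per_device.items():
        times = np.array([t for t, _ in rows])
        mats = np.array([m for _, m in rows]).reshape(-1, 4, 4)
        order = np.argsort(times, kind="stable")
        track = DeviceTrack(times[order], mats[order][:, :3, :3], mats[order][:, :3, 3])
        track.validate_rigidity()
        tracks[device] = track
    triggers.sort(key=lambda ev: ev.time)
    return PoseStream(tracks, triggers)


def write_pose_stream(stream: PoseStream, path) -> None:
    """Write all samples and triggers as JSONL, globally ordered by time."""
    rows: list[tuple[float, int, str]] = []
    for device, track in stream.tracks.items():
        mats = np.zeros((len(track), 4, 4))
        mats[:, :3, :3] = track.rotations
        mats[:, :3, 3] = track.translations
        mats[:, 3, 3] = 1.0
        for i in range(len(track)):
            rec = {
                "t": float(track.times[i]),
                "device": device,
                "T": [float(v) for v in mats[i].ravel()],
            }
            rows.append((float(track.times[i]), 0, json.dumps(rec)))
    for ev in stream.triggers:
        rec = {"t": ev.time, "device": ev.device, "event": "trigger"}
        rows.append((ev.time, 1, json.dumps(rec)))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        for _, _, line in rows:
            fh.write(line + "\n")
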