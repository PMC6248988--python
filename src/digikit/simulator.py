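"""Synthetic 6-DOF digitization scenarios with known ground truth.

Generates an electrode layout on an ellipsoidal head, a rigid head
trajectory, one or two head trackers rigidly mounted on the head, and a
controller stream that visits every target with a fixed (known) endpoint
offset.  Noise is phenomenological: iid Gaussian translation jitter plus
an exponentially decaying post-movement transient after every transit.
Identical seed and config produce bit-identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.spatial.transform import Rotation, Slerp

from .errors import DigikitError
from .geometry import EndpointOffset, RigidTransform
from .montage import DEFAULT_FIDUCIAL_NAMES, Montage, biosemi128_labels
from .calibration import CalibrationSet
from .posestream import DeviceTrack, PoseStream, TriggerEvent
from .session import DigitizationSession, DigitizedPoint

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "HeadTrajectory",
    "generate_layout",
    "simulate_session",
    "simulate_calibration",
    "truth_session",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

CONTROLLER_ID = "controller"
TRACKER_IDS = ("tracker1", "tracker2")


@dataclass
class ScenarioConfig:
    """Everything needed to synthesize one digitization scenario."""

    n_electrodes: int = 128
    head_semiaxes_mm: tuple[float, float, float] = (80.0, 95.0, 88.0)  # x, y, z
    neighbor_spacing_mm: tuple[float, float] = (18.0, 25.0)
    endpoint_truth_mm: tuple[float, float, float] = (27.0, 0.0, -5.0)
    jitter_sigma_mm: float = 0.0
    tracker_jitter_sigma_mm: float | None = None  # defaults to jitter_sigma_mm
    transient_amplitude_mm: float = 0.0
    transient_decay_s: float = 0.5
    head_motion: list[dict] = field(default_factory=list)  # waypoints
    sample_rate_hz: float = 90.0
    dwell_s: float = 1.5
    transit_s: float = 0.5
    n_trackers: int = 0
    tracker_slip_mm: tuple[float, float, float] | None = None
    tracker_slip_time_s: float | None = None
    headshape_refiducials: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be positive")
        if any(a <= 0 for a in self.head_semiaxes_mm):
            raise ValueError("head semi-axes must be positive")
        if self.sample_rate_hz <= 0 or self.dwell_s <= 0 or self.transit_s < 0:
            raise ValueError("time scales must be positive")
        if self.jitter_sigma_mm < 0 or self.transient_amplitude_mm < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.n_trackers <= 2:
            raise ValueError("n_trackers must be 0, 1 or 2")

    @property
    def tracker_sigma(self) -> float:
        if self.tracker_jitter_sigma_mm is None:
            return self.jitter_sigma_mm
        return self.tracker_jitter_sigma_mm

    def tracker_ids(self) -> tuple[str, ...]:
        return TRACKER_IDS[: self.n_trackers]

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("head_semiaxes_mm", "neighbor_spacing_mm", "endpoint_truth_mm"):
            d[k] = list(d[k])
        if d["tracker_slip_mm"] is not None:
            d["tracker_slip_mm"] = list(d["tracker_slip_mm"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for k in ("head_semiaxes_mm", "neighbor_spacing_mm", "endpoint_truth_mm",
                  "tracker_slip_mm"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class HeadTrajectory:
    """Piecewise constant-velocity rigid head motion.

    Waypoints are (time, transform); translation is interpolated
    linearly and rotation by slerp between consecutive waypoints, held
    constant outside the waypoint span.  An empty waypoint list means a
    static head at identity.
    """

    times: np.ndarray
    transforms: list[RigidTransform]

    @classmethod
    def static(cls) -> "HeadTrajectory":
        return cls(np.array([0.0]), [RigidTransform.identity()])

    @classmethod
    def from_waypoints(cls, waypoints: list[dict]) -> "HeadTrajectory":
        if not waypoints:
            return cls.static()
        times, transforms = [], []
        for wp in waypoints:
            times.append(float(wp["t"]))
            rotvec = np.deg2rad(np.asarray(wp.get("rotvec_deg", (0, 0, 0)), dtype=float))
            transforms.append(
                RigidTransform(
                    Rotation.from_rotvec(rotvec).as_matrix(),
                    np.asarray(wp.get("translation_mm", (0, 0, 0)), dtype=float),
                )
            )
        order = np.argsort(times)
        return cls(np.asarray(times, dtype=float)[order], [transforms[i] for i in order])

    def poses_at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rotations (N,3,3) and translations (N,3) at the given times."""
        t = np.asarray(t, dtype=float)
        if len(self.transforms) == 1:
            tr = self.transforms[0]
            return (
                np.broadcast_to(tr.rotation, (len(t), 3, 3)).copy(),
                np.broadcast_to(tr.translation, (len(t), 3)).copy(),
            )
        tc = np.clip(t, self.times[0], self.times[-1])
        rots = Rotation.from_matrix(np.array([tr.rotation for tr in self.transforms]))
        r = Slerp(self.times, rots)(tc).as_matrix()
        trans_wp = np.array([tr.translation for tr in self.transforms])
        trans = np.column_stack(
            [np.interp(tc, self.times, trans_wp[:, k]) for k in range(3)]
        )
        return r, trans


@dataclass
class GroundTruth:
    """Everything the scenario knows that the pipeline must recover."""

    electrodes: dict[str, np.ndarray]      # label -> head-frame position (mm)
    fiducials: dict[str, np.ndarray]       # name -> head-frame position (mm)
    tracker_mounts: dict[str, RigidTransform]  # tracker frame -> head frame
    endpoint: EndpointOffset
    trajectory: HeadTrajectory
    config: ScenarioConfig

    def target_plan(self) -> list[tuple[str, str, np.ndarray]]:
        """(label, role, head-frame position) in canonical measurement order."""
        plan = [(n, "fiducial", self.fiducials[n]) for n in DEFAULT_FIDUCIAL_NAMES]
        plan += [(l, "electrode", p) for l, p in self.electrodes.items()]
        for _ in range(self.config.headshape_refiducials):
            plan += [(n, "refiducial", self.fiducials[n]) for n in DEFAULT_FIDUCIAL_NAMES]
        return plan

    def to_dict(self) -> dict:
        return {
            "unit": "mm",
            "electrodes": {k: [float(x) for x in v] for k, v in self.electrodes.items()},
            "fiducials": {k: [float(x) for x in v] for k, v in self.fiducials.items()},
            "tracker_mounts": {
                k: [list(map(float, row)) for row in v.as_matrix()]
                for k, v in self.tracker_mounts.items()
            },
            "endpoint_mm": [float(v) for v in self.endpoint.offset],
            "config": self.config.to_dict(),
        }


def _ellipsoid_point(direction: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    """Surface point along `direction` from the ellipsoid center."""
    d = np.asarray(direction, dtype=float)
    s = 1.0 / np.sqrt(np.sum((d / semiaxes) ** 2))
    return s * d


def _electrode_labels(n: int) -> list[str]:
    if n == 128:
        return biosemi128_labels()
    return [f"E{i}" for i in range(1, n + 1)]


def generate_layout(cfg: ScenarioConfig) -> GroundTruth:
    """Quasi-uniform electrode layout on the upper ellipsoid + fiducials.

    Points follow a Fibonacci spiral over the upper cap, so consecutive
    labels run in descending rings like a radial cap montage.  The median
    nearest-neighbor spacing must land inside ``cfg.neighbor_spacing_mm``
    or the configuration is rejected as infeasible.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_electrodes
    semiaxes = np.asarray(cfg.head_semiaxes_mm, dtype=float)

    z_top, z_cut = 0.995, -0.05  # unit-sphere cap holding the cap electrodes
    i = np.arange(n)
    z = z_top - (z_top - z_cut) * (i + 0.5) / n
    phi = i * GOLDEN_ANGLE
    rho = np.sqrt(1.0 - z**2)
    unit = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    pts = unit * semiaxes  # exact ellipsoid surface points

    if n >= 4:
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
        np.fill_diagonal(d2, np.inf)
        median_nn = float(np.median(np.sqrt(d2.min(axis=1))))
        lo, hi = cfg.neighbor_spacing_mm
        if n >= 32 and not lo <= median_nn <= hi:
            raise DigikitError(
                f"infeasible layout: median neighbor spacing {median_nn:.1f} mm "
                f"outside [{lo}, {hi}] mm for head {tuple(semiaxes)} with {n} electrodes"
            )

    labels = _electrode_labels(n)
    electrodes = {lab: pts[k] for k, lab in enumerate(labels)}

    fiducials = {
        "nasion": _ellipsoid_point(np.array([0.0, 1.0, -0.05]), semiaxes),
        "lpa": _ellipsoid_point(np.array([-1.0, 0.02, -0.12]), semiaxes),
        "rpa": _ellipsoid_point(np.array([1.0, 0.02, -0.12]), semiaxes),
    }

    mounts: dict[str, RigidTransform] = {}
    for k, tid in enumerate(TRACKER_IDS):
        side = -1.0 if k == 0 else 1.0
        base = _ellipsoid_point(np.array([side * 0.45, 0.85, 0.30]), semiaxes)
        rot = Rotation.from_rotvec(rng.uniform(-0.5, 0.5, size=3)).as_matrix()
        mounts[tid] = RigidTransform(rot, base + base / np.linalg.norm(base) * 10.0)

    return GroundTruth(
        electrodes=electrodes,
        fiducials=fiducials,
        tracker_mounts=mounts,
        endpoint=EndpointOffset(np.asarray(cfg.endpoint_truth_mm, dtype=float)),
        trajectory=HeadTrajectory.from_waypoints(cfg.head_motion),
        config=cfg,
    )


def _segment_rotations(r_from: np.ndarray, r_to: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 3, 3))
    key = Rotation.from_matrix(np.array([r_from, r_to]))
    frac = (np.arange(n) + 1.0) / n
    return Slerp([0.0, 1.0], key)(frac).as_matrix()


def simulate_session(truth: GroundTruth, cfg: ScenarioConfig | None = None) -> PoseStream:
    """Emit controller + tracker streams visiting every target in order.

    The endpoint dwells >= `dwell_s` at each target (stationary in the
    moving head frame), with a trigger at the end of each dwell, linear
    transits between targets, per-sample Gaussian translation jitter, and
    a decaying post-movement transient starting at each arrival.
    """
    cfg = truth.config if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed + 1)
    rate = cfg.sample_rate_hz
    dwell_n = max(int(round(cfg.dwell_s * rate)), 2)
    transit_n = max(int(round(cfg.transit_s * rate)), 1)
    plan = truth.target_plan()

    seg_len = transit_n + dwell_n
    n_total = seg_len * len(plan)
    times = np.arange(n_total) / rate

    # endpoint path in head frame + controller orientation keyframes
    park = np.array([0.0, 0.0, truth.config.head_semiaxes_mm[2] + 150.0])
    p_head = np.empty((n_total, 3))
    ctrl_rot = np.empty((n_total, 3, 3))
    trigger_idx: list[int] = []
    prev_pos = park
    prev_rot = Rotation.random(rng=np.random.default_rng(cfg.seed + 2)).as_matrix()
    rot_rng = np.random.default_rng(cfg.seed + 3)
    transient_starts: list[int] = []
    for k, (_, _, pos) in enumerate(plan):
        s = k * seg_len
        frac = ((np.arange(transit_n) + 1.0) / transit_n)[:, None]
        p_head[s : s + transit_n] = prev_pos + frac * (pos - prev_pos)
        p_head[s + transit_n : s + seg_len] = pos
        next_rot = Rotation.random(rng=rot_rng).as_matrix()
        ctrl_rot[s : s + transit_n] = _segment_rotations(prev_rot, next_rot, transit_n)
        ctrl_rot[s + transit_n : s + seg_len] = next_rot
        transient_starts.append(s + transit_n)
        trigger_idx.append(s + seg_len - 1)
        prev_pos, prev_rot = pos, next_rot

    head_r, head_t = truth.trajectory.poses_at(times)
    endpoint_global = np.einsum("nij,nj->ni", head_r, p_head) + head_t

    # post-movement transient on the controller, fixed random direction per dwell
    transient = np.zeros((n_total, 3))
    if cfg.transient_amplitude_mm > 0:
        for s in transient_starts:
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            seg = slice(s, min(s + seg_len, n_total))
            dt = times[seg] - times[s]
            transient[seg] = u * cfg.transient_amplitude_mm * np.exp(
                -dt / cfg.transient_decay_s
            )[:, None]

    ctrl_trans = (
        endpoint_global
        - np.einsum("nij,j->ni", ctrl_rot, truth.endpoint.offset)
        + transient
    )
    if cfg.jitter_sigma_mm > 0:
        ctrl_trans = ctrl_trans + rng.normal(0.0, cfg.jitter_sigma_mm, (n_total, 3))

    tracks = {CONTROLLER_ID: DeviceTrack(times, ctrl_rot, ctrl_trans)}

    for tid in cfg.tracker_ids():
        mount = truth.tracker_mounts[tid]
        mount_r = np.broadcast_to(mount.rotation, (n_total, 3, 3))
        mount_t = np.broadcast_to(mount.translation, (n_total, 3)).copy()
        if (
            cfg.tracker_slip_mm is not None
            and cfg.tracker_slip_time_s is not None
            and tid == cfg.tracker_ids()[-1]
        ):
            slipped = times >= cfg.tracker_slip_time_s
            mount_t[slipped] = mount.translation + np.asarray(
                cfg.tracker_slip_mm, dtype=float
            )
        rot = np.einsum("nij,njk->nik", head_r, mount_r)
        trans = np.einsum("nij,nj->ni", head_r, mount_t) + head_t
        if cfg.tracker_sigma > 0:
            trans = trans + rng.normal(0.0, cfg.tracker_sigma, (n_total, 3))
        tracks[tid] = DeviceTrack(times.copy(), rot, trans)

    triggers = [TriggerEvent(float(times[i]), CONTROLLER_ID) for i in trigger_idx]
    return PoseStream(tracks, triggers)


def simulate_calibration(
    endpoint: EndpointOffset | np.ndarray,
    n_poses: int = 10,
    rotation_spread_deg: float = 90.0,
    jitter_sigma_mm: float = 0.0,
    seed: int = 0,
    fixed_point: np.ndarray | None = None,
) -> CalibrationSet:
    """Poses whose transformed endpoint coincides at one fixed tip point.

    Rotations are drawn about alternating distinct axes with angles up to
    ``rotation_spread_deg/2``; a spread of zero deliberately produces a
    degenerate (identical-rotation) set for negative testing.
    """
    if n_poses < 3:
        raise ValueError("need at least 3 calibration poses")
    offset = endpoint.offset if isinstance(endpoint, EndpointOffset) else np.asarray(
        endpoint, dtype=float
    )
    rng = np.random.default_rng(seed)
    p = (
        np.asarray(fixed_point, dtype=float)
        if fixed_point is not None
        else rng.uniform(-500.0, 500.0, 3)
    )
    base = Rotation.random(rng=np.random.default_rng(seed + 10)).as_matrix()
    half = np.deg2rad(rotation_spread_deg) / 2.0
    axes = np.eye(3)
    transforms = []
    for i in range(n_poses):
        if rotation_spread_deg == 0.0:
            rot = base
        else:
            axis = axes[i % 3]
            angle = rng.uniform(-half, half)
            rot = base @ Rotation.from_rotvec(axis * angle).as_matrix()
        t = p - rot @ offset
        if jitter_sigma_mm > 0:
            t = t + rng.normal(0.0, jitter_sigma_mm, 3)
        transforms.append(RigidTransform(rot, t))
    return CalibrationSet(transforms)


def truth_session(truth: GroundTruth) -> DigitizationSession:
    """Ground-truth layout packaged as a reference session (head frame)."""
    montage = Montage(labels=list(truth.electrodes), name="ground-truth")
    session = DigitizationSession(montage=montage)
    for name, pos in truth.fiducials.items():
        session.add_fiducial(name, pos)
    for label, pos in truth.electrodes.items():
        session.add_electrode(
            DigitizedPoint(label=label, role="electrode", position=pos)
        )
    session.provenance = {"system": "simulator-ground-truth"}
    return session
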