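"""Digitization sessions: measured fiducials, electrodes, head-shape points.

A session tracks what has been measured against its montage, hands out
the next measurement target (fiducials first, then electrodes in montage
order, then free head-shape sampling), and persists losslessly to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, UnknownLabelError
from .montage import (
    DEFAULT_FIDUCIAL_NAMES,
    FiducialSet,
    Montage,
    aggregate_fiducials,
    save_sfp,
)

__all__ = ["DigitizedPoint", "DigitizationSession", "DONE"]

SCHEMA_VERSION = 1

#: Sentinel returned by next_target when the session is complete.
DONE = "__done__"

REFIDUCIAL_WARN_MM = 3.0


@dataclass
class DigitizedPoint:
    """One accepted measurement within a session."""

    label: str
    role: str                     # fiducial | electrode | headshape
    position: np.ndarray          # mm
    frame: str = "global"
    valid: bool = True
    stability_mm: float = 0.0
    window_n: int = 1
    time: float = 0.0
    rejected: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "role": self.role,
            "position_mm": [float(v) for v in self.position],
            "frame": self.frame,
            "valid": bool(self.valid),
            "stability_mm": float(self.stability_mm),
            "window_n": int(self.window_n),
            "time_s": float(self.time),
            "rejected": bool(self.rejected),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DigitizedPoint":
        return cls(
            label=d["label"],
            role=d["role"],
            position=np.array(d["position_mm"], dtype=float),
            frame=d.get("frame", "global"),
            valid=bool(d.get("valid", True)),
            stability_mm=float(d.get("stability_mm", 0.0)),
            window_n=int(d.get("window_n", 1)),
            time=float(d.get("time_s", 0.0)),
            rejected=bool(d.get("rejected", False)),
        )


@dataclass
class DigitizationSession:
    """State of one digitization run against a montage."""

    montage: Montage
    fiducials: FiducialSet = None  # type: ignore[assignment]
    electrodes: dict[str, DigitizedPoint] = field(default_factory=dict)
    headshape: list[DigitizedPoint] = field(default_factory=list)
    tracker_ids: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.fiducials is None:
            self.fiducials = FiducialSet(names=DEFAULT_FIDUCIAL_NAMES)

    # -- measurement flow ---------------------------------------------
    def next_target(self, remeasure: str | None = None) -> str:
        """Next label to measure: fiducials, then montage order, then DONE.

        Already-measured labels are skipped unless `remeasure` names one.
        """
        if remeasure is not None:
            if remeasure in self.fiducials.names or remeasure in self.montage.labels:
                return remeasure
            raise UnknownLabelError(f"unknown label {remeasure!r}")
        for name in self.fiducials.names:
            if not self.fiducials.measured(name):
                return name
        for label in self.montage.labels:
            if label not in self.electrodes:
                return label
        return DONE

    def add_fiducial(self, name: str, position: np.ndarray) -> None:
        self.fiducials.add(name, position)

    def add_electrode(self, point: DigitizedPoint) -> None:
        if point.label not in self.montage.labels:
            raise UnknownLabelError(
                f"electrode {point.label!r} not in montage {self.montage.name!r}"
            )
        self.electrodes[point.label] = point

    def add_headshape(self, point: DigitizedPoint) -> None:
        self.headshape.append(point)

    def add_headshape_refiducial(
        self, name: str, position: np.ndarray, warn_mm: float = REFIDUCIAL_WARN_MM
    ) -> None:
        """Record a fiducial re-measurement as a head-shape point.

        Tagged with the fiducial name; the aggregated fiducial itself is
        untouched.  A consistency warning is recorded when the re-measured
        point sits farther than `warn_mm` from the aggregate.
        """
        if name not in self.fiducials.names:
            raise UnknownLabelError(f"unknown fiducial {name!r}")
        if not self.fiducials.measured(name):
            raise UnknownLabelError(f"fiducial {name!r} not yet measured")
        position = np.asarray(position, dtype=float)
        agg = self.fiducials.aggregate()[name]
        dist = float(np.linalg.norm(position - agg))
        if dist > warn_mm:
            self.warnings.append(
                f"head-shape re-measurement of {name!r} is {dist:.2f} mm from "
                f"its aggregate (> {warn_mm:.1f} mm)"
            )
        self.headshape.append(
            DigitizedPoint(label=name, role="headshape", position=position)
        )

    # -- queries ------------------------------------------------------
    def fiducial_positions(self) -> dict[str, np.ndarray]:
        means, _, warnings = aggregate_fiducials(self.fiducials)
        for w in warnings:
            if w not in self.warnings:
                self.warnings.append(w)
        return means

    def usable_electrodes(self) -> dict[str, np.ndarray]:
        """Non-rejected electrode positions, in montage order."""
        return {
            label: self.electrodes[label].position
            for label in self.montage.labels
            if label in self.electrodes and not self.electrodes[label].rejected
        }

    def n_rejected(self) -> int:
        return sum(1 for p in self.electrodes.values() if p.rejected)

    # -- persistence --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "unit": "mm",
            "montage": {
                "name": self.montage.name,
                "labels": list(self.montage.labels),
                "template_positions_mm": {
                    k: [float(x) for x in v]
                    for k, v in self.montage.template_positions.items()
                },
            },
            "fiducials": {
                "names": list(self.fiducials.names),
                "repeats_mm": {
                    k: [[float(x) for x in p] for p in reps]
                    for k, reps in self.fiducials.repeats.items()
                },
            },
            "electrodes": [
                self.electrodes[l].to_dict()
                for l in self.montage.labels
                if l in self.electrodes
            ],
            "headshape": [p.to_dict() for p in self.headshape],
            "tracker_ids": list(self.tracker_ids),
            "provenance": self.provenance,
            "warnings": list(self.warnings),
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "DigitizationSession":
        if d.get("unit", "mm") != "mm":
            raise FormatError(f"unsupported session unit {d.get('unit')!r}")
        m = d["montage"]
        montage = Montage(
            labels=list(m["labels"]),
            template_positions={
                k: np.array(v, dtype=float)
                for k, v in m.get("template_positions_mm", {}).items()
            },
            name=m.get("name", ""),
        )
        fsrc = d.get("fiducials", {})
        fiducials = FiducialSet(
            names=tuple(fsrc.get("names", DEFAULT_FIDUCIAL_NAMES)),
            repeats={
                k: [np.array(p, dtype=float) for p in reps]
                for k, reps in fsrc.get("repeats_mm", {}).items()
            },
        )
        session = cls(
            montage=montage,
            fiducials=fiducials,
            tracker_ids=tuple(d.get("tracker_ids", ())),
            provenance=dict(d.get("provenance", {})),
            warnings=list(d.get("warnings", [])),
        )
        for rec in d.get("electrodes", []):
            session.electrodes[rec["label"]] = DigitizedPoint.from_dict(rec)
        for rec in d.get("headshape", []):
            session.headshape.append(DigitizedPoint.from_dict(rec))
        return session

    @classmethod
    def load(cls, path) -> "DigitizationSession":
        path = Path(path)
        try:
            with open(path, "r", encoding="utf-8") as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid session JSON: {exc.msg}", path) from exc
        if not isinstance(data, dict) or "montage" not in data:
            raise FormatError("not a digitization session file", path)
        return cls.from_dict(data)

    # -- exports ------------------------------------------------------
    def export_sfp(self, path, include_rejected: bool = False) -> None:
        rows = [(name, pos) for name, pos in self.fiducial_positions().items()]
        for label in self.montage.labels:
            pt = self.electrodes.get(label)
            if pt is None or (pt.rejected and not include_rejected):
                continue
            rows.append((label, pt.position))
        save_sfp(path, rows)

    def export_electrode_csv(self, path, include_rejected: bool = False) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("label,x_mm,y_mm,z_mm,valid,stability_mm,rejected\n")
            for label in self.montage.labels:
                pt = self.electrodes.get(label)
                if pt is None or (pt.rejected and not include_rejected):
                    continue
                x, y, z = (float(v) for v in pt.position)
                fh.write(
                    f"{label},{x!r},{y!r},{z!r},{int(pt.valid)},"
                    f"{float(pt.stability_mm)!r},{int(pt.rejected)}\n"
                )
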