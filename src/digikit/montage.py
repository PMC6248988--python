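"""EEG montage files and fiducial bookkeeping.

Supported montage dialects:

``.sfp``
    Whitespace-separated ``label x y z`` rows (BESA-style).  Rows whose
    labels are recognized fiducial names (``fidnz``/``nz``/``nasion``,
    ``fidt9``/``lpa``, ``fidt10``/``rpa``) are routed into fiducial
    templates rather than the electrode list.  Units assumed mm unless
    `unit_scale` overrides.
``.elc``
    ASA electrode files: ``NumberPositions=``, ``UnitPosition``,
    ``Positions:`` and ``Labels:`` sections.
``.csv``
    ``label,x,y,z`` with optional header row.

A label-only file (one label per line, any extension via format
``labels``) yields a montage without template positions.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = [
    "Montage",
    "FiducialSet",
    "load_montage",
    "save_sfp",
    "aggregate_fiducials",
    "biosemi128_labels",
    "DEFAULT_FIDUCIAL_NAMES",
]

DEFAULT_FIDUCIAL_NAMES = ("nasion", "lpa", "rpa")
FIDUCIAL_SPREAD_WARN_MM = 3.0

# common aliases found in montage files, lowercased
_FIDUCIAL_ALIASES = {
    "nasion": "nasion", "nz": "nasion", "fidnz": "nasion",
    "lpa": "lpa", "fidt9": "lpa", "t9": "lpa",
    "rpa": "rpa", "fidt10": "rpa", "t10": "rpa",
}


def biosemi128_labels() -> list[str]:
    """The 128 BioSemi labels A1..A32, B1..B32, C1..C32, D1..D32 in cap order."""
    return [f"{bank}{i}" for bank in "ABCD" for i in range(1, 33)]


@dataclass
class Montage:
    """Ordered electrode labels plus optional template positions (mm)."""

    labels: list[str]
    template_positions: dict[str, np.ndarray] = field(default_factory=dict)
    fiducial_templates: dict[str, np.ndarray] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise FormatError(f"duplicate electrode labels: {dupes}")
        unknown = set(self.template_positions) - set(self.labels)
        if unknown:
            raise FormatError(
                f"template positions for labels not in montage: {sorted(unknown)}"
            )

    def __len__(self) -> int:
        return len(self.labels)


def _parse_sfp(path: Path, unit_scale: float) -> Montage:
    labels, templates, fids = [], {}, {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    n_rows = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(
                f"expected 'label x y z', got {len(parts)} fields", path, lineno
            )
        label = parts[0]
        try:
            xyz = np.array([float(v) for v in parts[1:]]) * unit_scale
        except ValueError as exc:
            raise FormatError(f"non-numeric coordinate: {exc}", path, lineno) from exc
        n_rows += 1
        canon = _FIDUCIAL_ALIASES.get(label.lower())
        if canon is not None:
            fids[canon] = xyz
        else:
            if label in templates:
                raise FormatError(f"duplicate label {label!r}", path, lineno)
            labels.append(label)
            templates[label] = xyz
    if n_rows == 0:
        raise FormatError("empty montage file", path)
    return Montage(labels, templates, fids, name=path.stem)


def _parse_elc(path: Path) -> Montage:
    positions: list[np.ndarray] = []
    labels: list[str] = []
    scale = 1.0
    section = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            low = line.lower()
            if low.startswith("numberpositions"):
                continue
            if low.startswith("unitposition"):
                unit = line.split()[-1].lower()
                scale = {"mm": 1.0, "cm": 10.0, "m": 1000.0}.get(unit)
                if scale is None:
                    raise FormatError(f"unknown unit {unit!r}", path, lineno)
                continue
            if low.startswith("positions"):
                section = "positions"
                continue
            if low.startswith("labels"):
                section = "labels"
                continue
            if section == "positions":
                fieldsq = line.replace(":", " ").split()
                nums = fieldsq[-3:]
                try:
                    positions.append(np.array([float(v) for v in nums]) * scale)
                except ValueError as exc:
                    raise FormatError(f"bad position row: {exc}", path, lineno) from exc
                if len(fieldsq) == 4:
                    labels.append(fieldsq[0])
            elif section == "labels":
                labels.extend(line.split())
            else:
                raise FormatError("content outside any section", path, lineno)
    if not positions:
        raise FormatError("no positions found", path)
    if len(labels) != len(positions):
        raise FormatError(
            f"{len(labels)} labels but {len(positions)} positions", path
        )
    elabels, templates, fids = [], {}, {}
    for label, xyz in zip(labels, positions):
        canon = _FIDUCIAL_ALIASES.get(label.lower())
        if canon is not None:
            fids[canon] = xyz
        else:
            elabels.append(label)
            templates[label] = xyz
    return Montage(elabels, templates, fids, name=path.stem)


def _parse_csv(path: Path, unit_scale: float) -> Montage:
    labels, templates, fids = [], {}, {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = _csv.reader(fh)
        rows = [(i + 1, row) for i, row in enumerate(reader) if row and any(row)]
    if not rows:
        raise FormatError("empty montage file", path)
    start = 0
    first = [c.strip().lower() for c in rows[0][1]]
    if first[:1] == ["label"]:
        start = 1
    for lineno, row in rows[start:]:
        if len(row) != 4:
            raise FormatError(f"expected 4 columns, got {len(row)}", path, lineno)
        label = row[0].strip()
        try:
            xyz = np.array([float(v) for v in row[1:]]) * unit_scale
        except ValueError as exc:
            raise FormatError(f"non-numeric coordinate: {exc}", path, lineno) from exc
        canon = _FIDUCIAL_ALIASES.get(label.lower())
        if canon is not None:
            fids[canon] = xyz
        elif label in templates:
            raise FormatError(f"duplicate label {label!r}", path, lineno)
        else:
            labels.append(label)
            templates[label] = xyz
    if not labels and not fids:
        raise FormatError("no electrode rows", path)
    return Montage(labels, templates, fids, name=path.stem)


def _parse_labels(path: Path) -> Montage:
    labels = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                labels.append(line.split()[0])
    if not labels:
        raise FormatError("empty montage file", path)
    return Montage(labels, name=path.stem)


def load_montage(path, fmt: str | None = None, unit_scale: float = 1.0) -> Montage:
    """Load a montage file; format inferred from the extension by default."""
    path = Path(path)
    if not path.exists():
        raise FormatError("montage file not found", path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "sfp":
        return _parse_sfp(path, unit_scale)
    if fmt == "elc":
        return _parse_elc(path)
    if fmt == "csv":
        return _parse_csv(path, unit_scale)
    if fmt in ("labels", "txt"):
        return _parse_labels(path)
    raise FormatError(f"unsupported montage format {fmt!r}", path)


def save_sfp(path, rows: list[tuple[str, np.ndarray]]) -> None:
    """Write ``label x y z`` rows (mm) in the given order."""
    with open(path, "w", encoding="utf-8") as fh:
        for label, xyz in rows:
            x, y, z = (float(v) for v in xyz)
            fh.write(f"{label}\t{x!r}\t{y!r}\t{z!r}\n")


@dataclass
class FiducialSet:
    """Named anatomical landmarks, each possibly measured repeatedly."""

    names: tuple[str, ...] = DEFAULT_FIDUCIAL_NAMES
    repeats: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def add(self, name: str, position: np.ndarray) -> None:
        if name not in self.names:
            raise FormatError(f"unknown fiducial {name!r} (have {self.names})")
        self.repeats.setdefault(name, []).append(np.asarray(position, dtype=float))

    def measured(self, name: str) -> bool:
        return bool(self.repeats.get(name))

    def aggregate(self) -> dict[str, np.ndarray]:
        """Mean position per measured fiducial."""
        return {n: np.mean(reps, axis=0) for n, reps in self.repeats.items() if reps}

    def spreads(self) -> dict[str, float]:
        """Max pairwise distance among repeats, per fiducial."""
        out = {}
        for n, reps in self.repeats.items():
            if not reps:
                continue
            pts = np.asarray(reps)
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
            out[n] = float(d.max())
        return out


def aggregate_fiducials(
    fiducials: FiducialSet, warn_threshold_mm: float = FIDUCIAL_SPREAD_WARN_MM
) -> tuple[dict[str, np.ndarray], dict[str, float], list[str]]:
    """Aggregate repeated fiducial measurements.

    Returns (mean positions, per-fiducial spread, warnings for spreads
    above `warn_threshold_mm`).
    """
    means = fiducials.aggregate()
    spreads = fiducials.spreads()
    warnings = [
        f"fiducial {n!r} repeat spread {s:.2f} mm exceeds {warn_threshold_mm:.1f} mm"
        for n, s in spreads.items()
        if s > warn_threshold_mm
    ]
    return means, spreads, warnings
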