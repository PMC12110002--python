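"""Labeled 3D landmark sets and 3DSlicer-compatible file I/O.

Landmarks are stored internally in LPS millimetres. 3DSlicer fiducial files
(.fcsv and markups JSON) declare their own coordinate system — modern Slicer
writes RAS by default — and points are sign-flipped on the first two axes
when converting. A plain CSV fallback (``label,x,y,z,frame``) is also
supported.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import LandmarkParseError
from .volume import ras_to_lps, lps_to_ras

__all__ = ["LandmarkSet", "read_landmarks", "write_fcsv", "write_markups_json", "write_csv"]


@dataclass(frozen=True)
class LandmarkSet:
    """Labeled physical points (mm). ``frame`` records the stored convention.

    Internally the package always constructs LPS sets; RAS only appears
    transiently during file import/export.
    """

    labels: tuple[str, ...]
    points: np.ndarray
    frame: str = "LPS"

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != len(points):
            raise LandmarkParseError(
                f"{len(labels)} labels for {len(points)} points"
            )
        if len(points) < 1:
            raise LandmarkParseError("landmark set must contain at least one point")
        if len(set(labels)) != len(labels):
            raise LandmarkParseError(f"duplicate landmark labels in {labels}")
        if not np.all(np.isfinite(points)):
            raise LandmarkParseError("landmark coordinates must be finite")
        if self.frame not in ("LPS", "RAS"):
            raise LandmarkParseError(f"unknown coordinate frame {self.frame!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points", points)

    def __len__(self) -> int:
        return len(self.labels)

    def to_lps(self) -> "LandmarkSet":
        if self.frame == "LPS":
            return self
        return LandmarkSet(self.labels, ras_to_lps(self.points), "LPS")

    def to_ras(self) -> "LandmarkSet":
        if self.frame == "RAS":
            return self
        return LandmarkSet(self.labels, lps_to_ras(self.points), "RAS")


def _read_fcsv(path) -> LandmarkSet:
    frame = "RAS"  # Slicer default when no CoordinateSystem header is present
    labels: list[str] = []
    points: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip()
                if header.lower().startswith("coordinatesystem"):
                    value = header.split("=", 1)[-1].strip()
                    if value in ("RAS", "0"):
                        frame = "RAS"
                    elif value in ("LPS", "1"):
                        frame = "LPS"
                    else:
                        raise LandmarkParseError(
                            f"{path}:{lineno}: unknown coordinate system {value!r}"
                        )
                continue
            cols = line.split(",")
            if len(cols) < 4:
                raise LandmarkParseError(f"{path}:{lineno}: expected >= 4 columns, got {len(cols)}")
            try:
                xyz = [float(c) for c in cols[1:4]]
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: non-numeric position") from exc
            # fcsv column 12 (index 11) is the display label when present
            label = cols[11].strip() if len(cols) > 11 and cols[11].strip() else cols[0].strip()
            labels.append(label)
            points.append(xyz)
    if not points:
        raise LandmarkParseError(f"{path}: no fiducial rows found")
    return LandmarkSet(tuple(labels), np.array(points), frame).to_lps()


def _read_markups_json(path) -> LandmarkSet:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise LandmarkParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        markup = doc["markups"][0]
        frame = markup.get("coordinateSystem", "RAS")
        cps = markup["controlPoints"]
        labels = [cp["label"] for cp in cps]
        points = [cp["position"] for cp in cps]
    except (KeyError, IndexError, TypeError) as exc:
        raise LandmarkParseError(f"{path}: missing markups structure: {exc}") from exc
    if frame not in ("RAS", "LPS"):
        raise LandmarkParseError(f"{path}: unknown coordinate system {frame!r}")
    return LandmarkSet(tuple(labels), np.array(points, dtype=float), frame).to_lps()


def _read_csv(path) -> LandmarkSet:
    labels: list[str] = []
    points: list[list[float]] = []
    frame = "LPS"
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "label":
                continue
            if len(row) < 4:
                raise LandmarkParseError(f"{path}:{lineno}: expected label,x,y,z[,frame]")
            try:
                xyz = [float(c) for c in row[1:4]]
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: non-numeric position") from exc
            labels.append(row[0].strip())
            points.append(xyz)
            if len(row) > 4 and row[4].strip():
                frame = row[4].strip().upper()
    if not points:
        raise LandmarkParseError(f"{path}: no landmark rows found")
    return LandmarkSet(tuple(labels), np.array(points), frame).to_lps()


def read_landmarks(path) -> LandmarkSet:
    """Read .fcsv, Slicer markups .json, or plain .csv landmarks; returns LPS."""
    p = str(path)
    if p.endswith(".fcsv"):
        return _read_fcsv(p)
    if p.endswith(".json") or p.endswith(".mrk.json"):
        return _read_markups_json(p)
    if p.endswith(".csv"):
        return _read_csv(p)
    raise LandmarkParseError(f"unrecognized landmark file extension: {p}")


def write_fcsv(lm: LandmarkSet, path) -> None:
    """Write a 3DSlicer .fcsv fiducial file (RAS, Slicer's native frame)."""
    ras = lm.to_ras()
    with open(path, "w") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# CoordinateSystem = RAS\n")
        fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
        for i, (label, p) in enumerate(zip(ras.labels, ras.points)):
            fh.write(
                f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.10g},{p[1]:.10g},{p[2]:.10g},"
                f"0,0,0,1,1,1,0,{label},,\n"
            )


def write_markups_json(lm: LandmarkSet, path) -> None:
    """Write a Slicer markups JSON file (LPS declared explicitly)."""
    lps = lm.to_lps()
    doc = {
        "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json#",
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": "LPS",
                "controlPoints": [
                    {"id": str(i + 1), "label": label, "position": list(map(float, p))}
                    for i, (label, p) in enumerate(zip(lps.labels, lps.points))
                ],
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def write_csv(lm: LandmarkSet, path) -> None:
    lps = lm.to_lps()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y", "z", "frame"])
        for label, p in zip(lps.labels, lps.points):
            writer.writerow([label, f"{p[0]:.10g}", f"{p[1]:.10g}", f"{p[2]:.10g}", "LPS"])


def check_label_correspondence(fixed: LandmarkSet, moving: LandmarkSet) -> None:
    """Warn when paired-by-order sets carry mismatched label names."""
    if fixed.labels != moving.labels:
        warnings.warn(
            "landmark labels differ between fixed and moving sets; "
            "pairing is by file order",
            stacklevel=3,
        )
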