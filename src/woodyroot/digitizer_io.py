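"""Parsing of 3-D digitizer point files and topology reconstruction.

The digitizer protocol records one point per line as

    <dot-ID> <organ> <x> <y> <z>

with coordinates in cm in the *digitizer frame* (x pointing vertically
downward).  Lines starting with ``#`` are comments; an optional header
``# soil_ref=<dot-ID>`` names the stem point marking the soil horizon
(default: stem point ``1``).

ID dialect
----------
Stem points carry plain integer IDs (0 = grafting point, 1 = soil horizon,
2, 3, ... = basal points of the cutting).  A root point's ID is its axis's
ID prefix plus a 1-based running point index, and an axis's ID prefix is the
full ID of the point on the parent where it branches: axis ``2.1.3``
branches at point 3 of axis ``2.1``.  Branch points are recorded twice — the
first point of a lateral duplicates the branch point on the lower-order root
("double point") — and the duplicate pair is merged to the parent's
coordinates during reconstruction, its deviation being retained as a
human-error measurement.
"""

from __future__ import annotations

import re
import warnings
from typing import IO, Iterable, Optional, Union

import numpy as np

from .core import Axis, AxisId, PointRecord, RootSystem

__all__ = [
    "DigitizerParseError",
    "TopologyError",
    "parse_points",
    "read_digitizer_file",
    "build_root_system",
    "segment_lengths",
    "digitizer_to_soil_frame",
]

DEFAULT_SOIL_REF: tuple[int, ...] = (1,)
DEFAULT_MERGE_TOLERANCE = 1.0  # cm; above the worst reported band mean (0.351 cm)

_SOIL_REF_RE = re.compile(r"#\s*soil_ref\s*=\s*([\d.]+)")
_ORGANS = {"stem", "root"}


class DigitizerParseError(ValueError):
    """Malformed digitizer file content, carrying the offending line number."""

    def __init__(self, line_no: int, message: str) -> None:
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class TopologyError(ValueError):
    """Inconsistent point hierarchy (orphan laterals, missing stem, ...)."""


def _parse_id(token: str, line_no: int) -> tuple[int, ...]:
    try:
        parts = tuple(int(p) for p in token.split("."))
    except ValueError:
        raise DigitizerParseError(line_no, f"malformed ID {token!r}") from None
    if any(p < 0 for p in parts):
        raise DigitizerParseError(line_no, f"negative ID component in {token!r}")
    return parts


def parse_points(stream: Union[IO[str], Iterable[str]]) -> list[PointRecord]:
    """Parse a digitizer point stream into :class:`PointRecord` objects.

    One record per non-blank, non-comment line, in file order.  Raises
    :class:`DigitizerParseError` naming the line on malformed input or
    duplicate full IDs.
    """
    records: list[PointRecord] = []
    seen: dict[tuple, int] = {}
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 5:
            raise DigitizerParseError(
                line_no, f"expected '<id> <organ> <x> <y> <z>', got {len(fields)} fields"
            )
        id_path = _parse_id(fields[0], line_no)
        organ = fields[1].lower()
        if organ not in _ORGANS:
            raise DigitizerParseError(line_no, f"unknown organ code {fields[1]!r}")
        try:
            xyz = np.array([float(v) for v in fields[2:5]])
        except ValueError:
            raise DigitizerParseError(line_no, "non-numeric coordinate") from None
        key = id_path
        if key in seen:
            raise DigitizerParseError(
                line_no, f"duplicate ID {fields[0]} (first seen on line {seen[key]})"
            )
        seen[key] = line_no
        records.append(PointRecord(id_path, organ, xyz, line_no))
    return records


def read_digitizer_file(source) -> tuple[list[PointRecord], tuple[int, ...]]:
    """Read a digitizer file (path or stream); return records and soil-ref ID."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    soil_ref = DEFAULT_SOIL_REF
    m = _SOIL_REF_RE.search(text)
    if m:
        soil_ref = tuple(int(p) for p in m.group(1).split("."))
    return parse_points(text.splitlines()), soil_ref


def digitizer_to_soil_frame(p: np.ndarray) -> np.ndarray:
    """Map digitizer-frame coordinates to the (untranslated) soil frame.

    The digitizer's x axis points vertically downward, so x -> -z; the
    remaining axes are relabelled to keep the frame right-handed
    (y -> x, z -> y).
    """
    p = np.asarray(p, dtype=float)
    return np.stack([p[..., 1], p[..., 2], -p[..., 0]], axis=-1)


def build_root_system(
    points: list[PointRecord],
    merge_tolerance: float = DEFAULT_MERGE_TOLERANCE,
    soil_ref: tuple[int, ...] = DEFAULT_SOIL_REF,
    genotype: Optional[str] = None,
    age_days: Optional[float] = None,
) -> tuple[RootSystem, list[float]]:
    """Reconstruct a :class:`RootSystem` from digitized points.

    Points are grouped into axes by ID prefix, double points at branchings
    are merged to the parent's coordinates (their Euclidean deviations are
    returned, in input order of the laterals), coordinates are transformed to
    the soil frame (z = 0 at the stem point named by ``soil_ref``), and root
    types are assigned from hierarchy depth.

    Deviations above ``merge_tolerance`` (cm) are warned about but still
    merged — they are themselves human-error measurements, not defects.
    """
    stem_pts: dict[int, np.ndarray] = {}
    axis_pts: dict[AxisId, dict[int, np.ndarray]] = {}
    for rec in points:
        pos = digitizer_to_soil_frame(rec.position)
        if rec.organ == "stem":
            if len(rec.id_path) != 1:
                raise TopologyError(
                    f"line {rec.line_no}: stem point ID must be a single integer, "
                    f"got {'.'.join(map(str, rec.id_path))}"
                )
            stem_pts[rec.id_path[0]] = pos
        else:
            if len(rec.id_path) < 2:
                raise TopologyError(
                    f"line {rec.line_no}: root point ID needs an axis prefix"
                )
            axis_pts.setdefault(rec.id_path[:-1], {})[rec.id_path[-1]] = pos

    if len(stem_pts) < 2:
        raise TopologyError("need at least two stem points (grafting point, soil ref)")
    if len(soil_ref) != 1 or soil_ref[0] not in stem_pts:
        raise TopologyError(
            f"soil reference point {'.'.join(map(str, soil_ref))} not found on the stem"
        )

    origin = stem_pts[soil_ref[0]].copy()
    stem_idx = sorted(stem_pts)
    stem_nodes = np.array([stem_pts[i] - origin for i in stem_idx])
    node_index_of: dict[tuple[int, ...], tuple[AxisId, int]] = {
        (i,): ((), pos) for pos, i in enumerate(stem_idx)
    }

    rs = RootSystem(genotype=genotype, age_days=age_days)
    rs.add_axis(Axis(axis_id=(), nodes=stem_nodes, root_type=0))

    deviations: list[float] = []
    for axis_id in sorted(axis_pts, key=lambda a: (len(a), a)):
        pts = axis_pts[axis_id]
        if 1 not in pts:
            raise TopologyError(
                f"axis {'.'.join(map(str, axis_id))}: missing first point (index 1)"
            )
        indices = sorted(pts)
        if indices != list(range(1, len(indices) + 1)):
            raise TopologyError(
                f"axis {'.'.join(map(str, axis_id))}: point indices not contiguous "
                f"from 1 ({indices})"
            )
        if axis_id not in node_index_of:
            raise TopologyError(
                f"orphan lateral {'.'.join(map(str, axis_id))}: no parent point "
                f"{'.'.join(map(str, axis_id))} was digitized"
            )
        parent_axis, parent_node = node_index_of[axis_id]
        parent_xyz = rs[parent_axis].nodes[parent_node]
        first = pts[1] - origin
        dev = float(np.linalg.norm(first - parent_xyz))
        deviations.append(dev)
        if dev > merge_tolerance:
            warnings.warn(
                f"axis {'.'.join(map(str, axis_id))}: double-point deviation "
                f"{dev:.3f} cm exceeds merge tolerance {merge_tolerance} cm "
                f"(merged anyway)",
                stacklevel=2,
            )
        if len(indices) < 2:
            raise TopologyError(
                f"axis {'.'.join(map(str, axis_id))}: needs at least 2 points"
            )
        nodes = np.vstack(
            [parent_xyz] + [pts[i] - origin for i in indices[1:]]
        )
        rs.add_axis(
            Axis(
                axis_id=axis_id,
                nodes=nodes,
                parent=parent_axis,
                parent_node=parent_node,
            )
        )
        # point i of this axis sits at node array position i - 1
        for i in indices:
            node_index_of[axis_id + (i,)] = (axis_id, i - 1)

    rs.validate()
    return rs, deviations


def segment_lengths(rs: RootSystem) -> dict[AxisId, np.ndarray]:
    """Per-axis Euclidean segment lengths (cm), keyed by axis ID."""
    return {axis_id: rs[axis_id].segment_lengths() for axis_id in sorted(rs.axes)}
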