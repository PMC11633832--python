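"""Reading and writing root systems in RSML (Root System Markup Language).

RSML is the standardized XML exchange format for root architecture:
``<rsml><metadata/><scene><plant><root>...`` with nested ``root`` elements,
each holding a ``geometry/polyline`` and ``properties``.  Nesting depth
encodes the root-type hierarchy (type-1 roots are children of the plant,
type-2 of type-1, and so on); branch attachment is encoded by the shared
node being repeated as the child's first polyline point.

Because RSML has no stem element, the stem is written as a top-level root
flagged with the property ``type = 0``; readers that ignore it still see a
valid root system.  Diameters are written per root (caliper measurement
practice), node emergence ages as an ``age`` function over the polyline.
"""

from __future__ import annotations

import datetime
import warnings
import xml.etree.ElementTree as ET
from typing import Optional, Union

import numpy as np

from .core import Axis, AxisId, RootSystem

__all__ = ["write_rsml", "read_rsml", "UNIT_TO_CM"]

UNIT_TO_CM = {
    "cm": 1.0,
    "mm": 0.1,
    "m": 100.0,
    "dm": 10.0,
    "um": 1e-4,
    "µm": 1e-4,
    "inch": 2.54,
    "pixel": 1.0,  # dimensionless fallback, taken as cm
}


def _fmt_id(axis_id: AxisId) -> str:
    return ".".join(map(str, axis_id)) if axis_id else "stem"


def _prop(parent: ET.Element, name: str, value) -> None:
    ET.SubElement(parent, "property", {"name": name, "value": str(value)})


def _write_root_element(container: ET.Element, rs: RootSystem, axis: Axis) -> None:
    root_el = ET.SubElement(
        container, "root", {"ID": _fmt_id(axis.axis_id), "label": _fmt_id(axis.axis_id)}
    )
    props = ET.SubElement(root_el, "properties")
    _prop(props, "type", axis.root_type)
    if axis.parent_node is not None:
        _prop(props, "parent-node", axis.parent_node)
    if axis.radius is not None:
        _prop(props, "diameter", 2.0 * axis.radius)
    geom = ET.SubElement(root_el, "geometry")
    poly = ET.SubElement(geom, "polyline")
    for x, y, z in axis.nodes:
        ET.SubElement(poly, "point", {"x": repr(float(x)), "y": repr(float(y)), "z": repr(float(z))})
    funcs = ET.SubElement(root_el, "functions")
    fn = ET.SubElement(funcs, "function", {"name": "age", "domain": "polyline"})
    for a in axis.node_ages:
        ET.SubElement(fn, "sample", {"value": repr(float(a))})
    for child in rs.children_of(axis.axis_id):
        _write_root_element(root_el, rs, child)


def write_rsml(rs: RootSystem, destination=None) -> ET.ElementTree:
    """Serialize a :class:`RootSystem` to RSML 1.0.

    ``destination`` may be a path or a writable binary/text stream; if
    ``None``, only the :class:`~xml.etree.ElementTree.ElementTree` is
    returned.  Coordinates are emitted in the soil frame (cm, z = 0 at the
    soil surface).
    """
    rs.validate()
    missing = sum(1 for a in rs if a.root_type > 0 and a.radius is None)
    if missing:
        warnings.warn(
            f"{missing} axes have no radius; their diameter property is omitted",
            stacklevel=2,
        )
    rsml = ET.Element("rsml")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "cm"
    ET.SubElement(meta, "resolution").text = "1"
    ET.SubElement(meta, "last-modified").text = datetime.date.today().isoformat()
    ET.SubElement(meta, "software").text = "woodyroot"
    scene = ET.SubElement(rsml, "scene")
    plant = ET.SubElement(scene, "plant", {"id": "1", "label": rs.genotype or "plant"})
    pprops = ET.SubElement(plant, "properties")
    if rs.genotype is not None:
        _prop(pprops, "genotype", rs.genotype)
    if rs.age_days is not None:
        _prop(pprops, "observation-age-days", rs.age_days)

    # the stem element recursively nests the whole axis hierarchy
    _write_root_element(plant, rs, rs.stem)

    tree = ET.ElementTree(rsml)
    ET.indent(tree)
    if destination is not None:
        if hasattr(destination, "write"):
            tree.write(destination, encoding="unicode", xml_declaration=False)
        else:
            tree.write(destination, encoding="utf-8", xml_declaration=True)
    return tree


# ---------------------------------------------------------------------------


def _read_properties(el: ET.Element) -> dict[str, str]:
    out = {}
    props = el.find("properties")
    if props is not None:
        for p in props.findall("property"):
            out[p.get("name", "")] = p.get("value", "")
    return out


def _read_polyline(el: ET.Element, scale: float) -> Optional[np.ndarray]:
    poly = el.find("geometry/polyline")
    if poly is None:
        return None
    pts = [
        [float(p.get("x", "nan")), float(p.get("y", "nan")), float(p.get("z", "nan"))]
        for p in poly.findall("point")
    ]
    if len(pts) < 2:
        return None
    return np.asarray(pts) * scale


def _read_ages(el: ET.Element, n: int) -> Optional[np.ndarray]:
    for fn in el.findall("functions/function"):
        if fn.get("name") in ("age", "node_age", "emergence_time"):
            vals = [float(s.get("value", "0")) for s in fn.findall("sample")]
            if len(vals) == n:
                return np.asarray(vals)
    return None


def _parse_axis_id(el: ET.Element) -> Optional[AxisId]:
    ident = el.get("ID") or el.get("id")
    if ident is None:
        return None
    if ident == "stem":
        return ()
    try:
        return tuple(int(p) for p in ident.split("."))
    except ValueError:
        return None


def read_rsml(source) -> RootSystem:
    """Parse an RSML document into a :class:`RootSystem`.

    Root types are inferred from element nesting depth, overridable by a
    ``type`` property.  Coordinates are converted to cm using the stated
    metadata unit.  Documents without a stem (``type = 0``) root get a
    synthetic vertical stem with one attachment node per top-level root.
    Polylines with fewer than 2 points are rejected with a warning.
    """
    tree = ET.parse(source)
    rsml = tree.getroot()
    unit_el = rsml.find("metadata/unit")
    unit = (unit_el.text or "cm").strip() if unit_el is not None else "cm"
    if unit not in UNIT_TO_CM:
        raise ValueError(f"unsupported RSML unit {unit!r}")
    scale = UNIT_TO_CM[unit]

    plant = rsml.find("scene/plant")
    if plant is None:
        raise ValueError("RSML document holds no scene/plant")
    pprops = _read_properties(plant)
    genotype = pprops.get("genotype") or plant.get("label")
    age_days = float(pprops["observation-age-days"]) if "observation-age-days" in pprops else None

    # first pass: flatten (element, depth) in document order
    flat: list[tuple[ET.Element, int, Optional[ET.Element]]] = []

    def _walk(el: ET.Element, depth: int, parent_el: Optional[ET.Element]) -> None:
        flat.append((el, depth, parent_el))
        for child in el.findall("root"):
            _walk(child, depth + 1, el)

    for top in plant.findall("root"):
        _walk(top, 1, None)

    rs = RootSystem(genotype=genotype, age_days=age_days)
    stem_entries = []
    root_entries = []
    for el, depth, parent_el in flat:
        props = _read_properties(el)
        rtype = int(float(props["type"])) if "type" in props else min(depth, 3)
        if rtype == 0:
            stem_entries.append((el, props))
        else:
            root_entries.append((el, depth, parent_el, props, rtype))

    el_to_id: dict[int, AxisId] = {}
    if stem_entries:
        el, props = stem_entries[0]
        nodes = _read_polyline(el, scale)
        if nodes is None:
            raise ValueError("stem root element has an invalid polyline")
        ages = _read_ages(el, len(nodes))
        radius = float(props["diameter"]) * scale / 2.0 if "diameter" in props else None
        rs.add_axis(
            Axis(axis_id=(), nodes=nodes, root_type=0, node_ages=ages, radius=radius)
        )
        el_to_id[id(el)] = ()
        if len(stem_entries) > 1:
            warnings.warn("multiple type-0 roots found; keeping the first", stacklevel=2)
    else:
        # synthesize a stem offering one attachment node per top-level root
        tops = [e for e, d, p, pr, t in root_entries if p is None]
        bases = []
        for e in tops:
            nodes = _read_polyline(e, scale)
            bases.append(nodes[0] if nodes is not None else np.zeros(3))
        if not bases:
            raise ValueError("RSML document holds no roots")
        stem_nodes = np.vstack([[0.0, 0.0, 0.0]] + bases)
        rs.add_axis(Axis(axis_id=(), nodes=stem_nodes, root_type=0))

    top_counter = 0
    for el, depth, parent_el, props, rtype in root_entries:
        nodes = _read_polyline(el, scale)
        if nodes is None:
            warnings.warn("skipping root with a polyline of < 2 points", stacklevel=2)
            continue
        if parent_el is None or id(parent_el) not in el_to_id:
            parent_id: AxisId = ()
        else:
            parent_id = el_to_id[id(parent_el)]
        parent_axis = rs[parent_id]
        if parent_el is None and not stem_entries:
            # synthetic stem: dedicated attachment node per top-level root
            top_counter += 1
            pnode = top_counter
        else:
            if "parent-node" in props:
                pnode = int(float(props["parent-node"]))
                if not 0 <= pnode < parent_axis.n_nodes:
                    pnode = int(
                        np.argmin(np.linalg.norm(parent_axis.nodes - nodes[0], axis=1))
                    )
            else:
                pnode = int(
                    np.argmin(np.linalg.norm(parent_axis.nodes - nodes[0], axis=1))
                )
        axis_id = _parse_axis_id(el)
        if axis_id is None or axis_id in rs.axes or axis_id == ():
            # regenerate from the dialect: child id = parent prefix + point index
            if parent_id == ():
                axis_id = (pnode,)
            else:
                axis_id = parent_id + (pnode + 1,)
            while axis_id in rs.axes:  # defensive de-duplication
                axis_id = axis_id[:-1] + (axis_id[-1] + 1000,)
        el_to_id[id(el)] = axis_id
        ages = _read_ages(el, len(nodes))
        radius = float(props["diameter"]) * scale / 2.0 if "diameter" in props else None
        nodes = nodes.copy()
        nodes[0] = parent_axis.nodes[pnode]  # shared node, exact by construction
        rs.add_axis(
            Axis(
                axis_id=axis_id,
                nodes=nodes,
                root_type=min(rtype, 3),
                node_ages=ages,
                radius=radius,
                parent=parent_id,
                parent_node=pnode,
            )
        )

    rs.validate()
    return rs
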