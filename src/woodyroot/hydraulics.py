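"""Root hydraulic properties: axial conductivity, SUF and Krs.

Three layers:

1. *Anatomy to conductivity*: theoretical axial conductivity of a root
   cross-section from its xylem vessel dimensions, by the Hagen-Poiseuille
   law adapted to elliptical conduits,

       Kh_theo = pi / (64 eta) * sum_i a_i^3 b_i^3 / (a_i^2 + b_i^2)

   with a_i, b_i the minor/major vessel diameters (m) and eta the dynamic
   viscosity of water at 20 degC (1.002e-9 MPa s); Kh in m^4 s^-1 MPa^-1.

2. *Conductivity to allometry*: a nonlinear least-squares power-law fit
   Kh = alpha * d^beta against root diameter, giving a diameter-dependent
   axial conductance for every simulated segment.

3. *Architecture to uptake*: the xylem water-flow network (Doussan
   formulation) solved on the segmented root system under uniform soil
   total potential and a fixed collar potential, yielding each segment's
   standard uptake fraction (SUF, summing to 1) and the whole-system
   conductance Krs (cm^3 cm^-1 d^-1, head-based units).

Radial conductivities (Lpr) are not genotype-specific measurements here:
the shipped defaults are a clearly-labelled synthetic placeholder table at
grapevine literature orders of magnitude, overridable via config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.optimize import curve_fit
from scipy.sparse.linalg import spsolve

from .core import AxisId, RootSystem
from .traits import distribute_by_depth

__all__ = [
    "ETA_WATER_20C",
    "CrossSection",
    "kh_theoretical",
    "convert_kh_units",
    "convert_kh_units_inverse",
    "PowerLawFit",
    "fit_kx_vs_diameter",
    "KrTable",
    "HydraulicParams",
    "HydraulicSolution",
    "solve_suf_krs",
    "suf_profile",
    "load_vessel_table",
]

#: dynamic viscosity of water at 20 degC, MPa s
ETA_WATER_20C = 1.002e-9

#: m^4 s^-1 MPa^-1  ->  cm^3 d^-1 per unit head gradient (cm/cm):
#: 9.80665e-3 MPa per m head * 1e-2 m/cm ... expressed directly:
#: multiply by 9.80665e-3 MPa/(m head) -> per cm-head/cm gradient,
#: 86400 s/d and 1e6 cm^3/m^3.
KH_M4_PER_S_MPA_TO_CM3_PER_D = 9.80665e-3 * 86400.0 * 1e6

#: Lpr in m s^-1 MPa^-1  ->  cm d^-1 per cm head (i.e. d^-1)
LPR_M_S_MPA_TO_PER_DAY = 100.0 * 86400.0 * 9.80665e-3 / 100.0 * 1.0
# (100 cm/m * 86400 s/d * (9.80665e-3/1) MPa per m head / (100 cm head per m head))


@dataclass
class CrossSection:
    """Xylem vessel dimensions of one root cross-section.

    ``vessels`` is an (n, 2) array of (minor, major) diameters in metres;
    builder methods accept micrometres, the unit of measurement tables.
    """

    vessels: np.ndarray  # (n, 2) in m
    root_diameter_cm: float
    genotype: str = ""
    zone: str = ""  # type1 | type2_suberized | type2_unsuberized

    def __post_init__(self) -> None:
        self.vessels = np.atleast_2d(np.asarray(self.vessels, dtype=float))
        if self.vessels.shape[1] != 2:
            raise ValueError("vessels must be (n, 2) minor/major diameters")
        if np.any(self.vessels <= 0):
            raise ValueError("vessel diameters must be positive")
        if np.any(self.vessels[:, 0] > self.vessels[:, 1] * (1 + 1e-9)):
            raise ValueError("minor diameter exceeds major diameter")

    @classmethod
    def from_micrometres(cls, minor_um, major_um, root_diameter_cm: float, **kw):
        v = np.column_stack([np.asarray(minor_um), np.asarray(major_um)]) * 1e-6
        return cls(v, root_diameter_cm, **kw)


def kh_theoretical(
    cs: Union[CrossSection, np.ndarray], eta: float = ETA_WATER_20C
) -> float:
    """Theoretical axial conductivity of a cross-section (m^4 s^-1 MPa^-1).

    Hagen-Poiseuille for elliptical conduits:
    ``pi/(64 eta) * sum a^3 b^3 / (a^2 + b^2)``; additive over vessels and
    equal to the classical ``pi d^4 / (128 eta)`` in the circular limit.
    """
    vessels = cs.vessels if isinstance(cs, CrossSection) else np.atleast_2d(cs)
    if len(vessels) == 0:
        raise ValueError("cross-section holds no vessels")
    a = vessels[:, 0]
    b = vessels[:, 1]
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("vessel diameters must be positive")
    return float(np.pi / (64.0 * eta) * np.sum(a**3 * b**3 / (a**2 + b**2)))


def convert_kh_units(kh_m4_s_mpa: float) -> float:
    """Kh from m^4 s^-1 MPa^-1 to cm^3 d^-1 per unit head gradient (cm/cm)."""
    if kh_m4_s_mpa < 0:
        raise ValueError("Kh must be non-negative")
    return kh_m4_s_mpa * KH_M4_PER_S_MPA_TO_CM3_PER_D


def convert_kh_units_inverse(kh_cm3_d: float) -> float:
    return kh_cm3_d / KH_M4_PER_S_MPA_TO_CM3_PER_D


# ---------------------------------------------------------------------------
# Kh vs diameter power law


@dataclass
class PowerLawFit:
    """``Kh(d) = alpha * d**beta`` with diameters in cm."""

    alpha: float
    beta: float
    rss: float = float("nan")
    alpha_se: float = float("nan")
    beta_se: float = float("nan")

    def __call__(self, diameter: float) -> float:
        return self.alpha * diameter**self.beta


def fit_kx_vs_diameter(
    samples: Sequence[tuple[float, float]], maxfev: int = 10_000
) -> PowerLawFit:
    """Fit a power law Kh = alpha * d^beta by damped nonlinear least squares.

    Initialized from ordinary least squares on log-log transformed data;
    needs >= 3 samples with distinct positive diameters.  Raises on
    non-positive diameters or failure to converge.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (diameter, Kh) samples")
    d, kh = arr[:, 0], arr[:, 1]
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    if len(np.unique(d)) < 3:
        raise ValueError("need >= 3 distinct diameters")
    if np.all(kh > 0):
        b0, loga0 = np.polyfit(np.log(d), np.log(kh), 1)
        p0 = (math.exp(loga0), b0)
    else:
        p0 = (max(kh.mean(), 1e-12), 1.0)

    def model(x, alpha, beta):
        return alpha * x**beta

    popt, pcov = curve_fit(model, d, kh, p0=p0, maxfev=maxfev)
    resid = kh - model(d, *popt)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    return PowerLawFit(
        alpha=float(popt[0]),
        beta=float(popt[1]),
        rss=float(np.sum(resid**2)),
        alpha_se=float(se[0]),
        beta_se=float(se[1]),
    )


def load_vessel_table(source) -> list[CrossSection]:
    """Load cross-sections from a CSV table.

    Expected columns: ``genotype, zone, root_diameter_cm, minor_um,
    major_um`` and optionally ``section`` (rows sharing all grouping keys
    form one cross-section).
    """
    df = pd.read_csv(source)
    keys = ["genotype", "zone", "root_diameter_cm"]
    if "section" in df.columns:
        keys.append("section")
    out = []
    for key, grp in df.groupby(keys, sort=True):
        out.append(
            CrossSection.from_micrometres(
                grp["minor_um"].to_numpy(),
                grp["major_um"].to_numpy(),
                root_diameter_cm=float(grp["root_diameter_cm"].iloc[0]),
                genotype=str(grp["genotype"].iloc[0]),
                zone=str(grp["zone"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# radial conductivity table


@dataclass
class KrTable:
    """Radial conductivity (d^-1: cm^3 per cm^2 surface per day per cm head)
    keyed by root type, with age classes as (upper age bound, value) pairs
    covering [0, inf)."""

    classes: dict[int, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for t, cl in self.classes.items():
            bounds = [b for b, _ in cl]
            if bounds != sorted(bounds) or not math.isinf(bounds[-1]):
                raise ValueError(f"type {t}: age classes must ascend and end at inf")
            if any(v < 0 for _, v in cl):
                raise ValueError("kr values must be non-negative")

    def __call__(self, root_type: int, age: float) -> float:
        cl = self.classes.get(root_type)
        if cl is None:
            return 0.0
        for bound, value in cl:
            if age < bound or math.isinf(bound):
                return value
        return cl[-1][1]


def default_kr_table() -> KrTable:
    """Synthetic placeholder radial conductivities (overridable via config).

    Order-of-magnitude values from the grapevine literature, converted from
    Lpr in m s^-1 MPa^-1 to head-based per-day units: unsuberized young
    segments ~1e-7, suberized ~1e-8, woody adventitious roots ~2e-9.
    Age classes: unsuberized below 30 days, suberized from 30 days.
    """
    un = 1e-7 * LPR_M_S_MPA_TO_PER_DAY
    su = 1e-8 * LPR_M_S_MPA_TO_PER_DAY
    woody = 2e-9 * LPR_M_S_MPA_TO_PER_DAY
    return KrTable(
        classes={
            0: [(math.inf, 0.0)],  # stem: no radial uptake
            1: [(math.inf, woody)],
            2: [(30.0, un), (math.inf, su)],
            3: [(30.0, un), (math.inf, su)],
        }
    )


@dataclass
class HydraulicParams:
    """Inputs for the water-flow solve: viscosity, Kh(d) fit, kr table."""

    eta: float = ETA_WATER_20C
    kx_fit: PowerLawFit = field(default_factory=lambda: PowerLawFit(16.0, 2.5))
    kr_table: KrTable = field(default_factory=default_kr_table)
    default_radius: float = 0.05  # cm, used when an axis has no radius

    def kx(self, diameter_cm: float) -> float:
        """Axial conductance of a segment of given diameter
        (cm^3 d^-1 per unit head gradient)."""
        return self.kx_fit(diameter_cm)

    @classmethod
    def from_yaml(cls, source) -> "HydraulicParams":
        if hasattr(source, "read"):
            obj = yaml.safe_load(source.read())
        else:
            with open(source, "r", encoding="utf-8") as fh:
                obj = yaml.safe_load(fh)
        kx = obj.get("kx_fit", {})
        fit = PowerLawFit(float(kx.get("alpha", 16.0)), float(kx.get("beta", 2.5)))
        classes = {}
        for t, cl in obj.get("kr_table", {}).items():
            classes[int(t)] = [
                (float("inf") if str(b).lower() in ("inf", ".inf") else float(b), float(v))
                for b, v in cl
            ]
        table = KrTable(classes) if classes else default_kr_table()
        return cls(
            eta=float(obj.get("eta", ETA_WATER_20C)),
            kx_fit=fit,
            kr_table=table,
            default_radius=float(obj.get("default_radius", 0.05)),
        )

    def to_yaml(self, destination=None) -> str:
        obj = {
            "eta": self.eta,
            "kx_fit": {"alpha": self.kx_fit.alpha, "beta": self.kx_fit.beta},
            "kr_table": {
                t: [["inf" if math.isinf(b) else b, v] for b, v in cl]
                for t, cl in self.kr_table.classes.items()
            },
            "default_radius": self.default_radius,
        }
        text = yaml.safe_dump(obj, sort_keys=False)
        if destination is not None:
            if hasattr(destination, "write"):
                destination.write(text)
            else:
                with open(destination, "w", encoding="utf-8") as fh:
                    fh.write(text)
        return text


# ---------------------------------------------------------------------------
# network solve


@dataclass
class HydraulicSolution:
    """Per-segment uptake solution of the root-system flow network."""

    segments: pd.DataFrame  # axis_id, type, length, radius, depth0, depth1, suf, inflow, psi
    krs: float  # cm^3 cm^-1 d^-1
    psi_soil: float  # cm head
    psi_collar: float  # cm head
    node_potentials: np.ndarray

    @property
    def suf(self) -> np.ndarray:
        return self.segments["suf"].to_numpy()


def solve_suf_krs(
    rs: RootSystem,
    hp: HydraulicParams,
    psi_soil: float = 0.0,
    psi_collar: float = -1000.0,
) -> HydraulicSolution:
    """Solve the xylem network for SUF and Krs (Doussan formulation).

    One unknown water potential per node; segment axial conductance
    ``kx(diameter)/length``, radial conductance ``kr(type, age) * 2 pi a l``
    split half/half between the segment's end nodes (trapezoidal lumping,
    second-order accurate against the continuous single-root solution).
    The collar (first stem node) is held at ``psi_collar``; the soil is at
    uniform total potential ``psi_soil`` (hydrostatic equilibrium, so
    gravity cancels).  By linearity, SUF and Krs are independent of the two
    potential values.
    """
    rs.validate()
    if psi_soil == psi_collar:
        raise ValueError("soil and collar potentials must differ")

    # global node indexing; lateral base nodes alias their parent node
    node_id: dict[tuple[AxisId, int], int] = {}
    coords: list[np.ndarray] = []
    order = sorted(rs.axes)
    for aid in order:
        ax = rs[aid]
        start = 0
        if ax.parent is not None:
            node_id[(aid, 0)] = node_id[(ax.parent, ax.parent_node)]
            start = 1
        for i in range(start, ax.n_nodes):
            node_id[(aid, i)] = len(coords)
            coords.append(ax.nodes[i])
    n_nodes = len(coords)
    collar = node_id[((), 0)] if () in rs.axes else 0

    seg_rows = []
    seg_nodes = []
    c_ax_list = []
    c_r_list = []
    for aid in order:
        ax = rs[aid]
        radius = ax.radius if ax.radius is not None else hp.default_radius
        diameter = 2.0 * radius
        ages = ax.node_ages
        for i in range(1, ax.n_nodes):
            gi, gk = node_id[(aid, i - 1)], node_id[(aid, i)]
            length = float(np.linalg.norm(ax.nodes[i] - ax.nodes[i - 1]))
            if length <= 0:
                continue
            age = float(0.5 * (ages[i - 1] + ages[i]))
            kx = hp.kx(diameter)
            kr = hp.kr_table(ax.root_type, age)
            c_ax = kx / length
            c_r = kr * 2.0 * math.pi * radius * length
            seg_rows.append(
                {
                    "axis_id": ".".join(map(str, aid)) if aid else "stem",
                    "seg": i - 1,
                    "type": ax.root_type,
                    "length": length,
                    "radius": radius,
                    "age": age,
                    "depth0": -float(ax.nodes[i - 1, 2]),
                    "depth1": -float(ax.nodes[i, 2]),
                    "c_ax": c_ax,
                    "c_r": c_r,
                }
            )
            seg_nodes.append((gi, gk))
            c_ax_list.append(c_ax)
            c_r_list.append(c_r)

    if not seg_rows:
        raise ValueError("root system holds no segments")
    if all(c == 0 for c in c_r_list):
        raise ValueError("all radial conductances are zero: singular system")

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_nodes)

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for (gi, gk), c_ax, c_r in zip(seg_nodes, c_ax_list, c_r_list):
        add(gi, gi, c_ax)
        add(gk, gk, c_ax)
        add(gi, gk, -c_ax)
        add(gk, gi, -c_ax)
        for g in (gi, gk):
            add(g, g, 0.5 * c_r)
            rhs[g] += 0.5 * c_r * psi_soil

    A = sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes))
    )
    # Dirichlet at the collar
    free = np.ones(n_nodes, dtype=bool)
    free[collar] = False
    psi = np.full(n_nodes, float(psi_collar))
    Aff = A[free][:, free]
    bf = rhs[free] - A[free][:, ~free] @ np.array([psi_collar])
    try:
        psi[free] = spsolve(Aff.tocsc(), bf)
    except Exception as exc:  # singular submatrix (isolated zero-conductance parts)
        raise ValueError(f"singular hydraulic system: {exc}") from exc
    if not np.all(np.isfinite(psi)):
        raise ValueError("singular hydraulic system: non-finite potentials")

    inflow = np.array(
        [
            0.5 * c_r * (psi_soil - psi[gi]) + 0.5 * c_r * (psi_soil - psi[gk])
            for (gi, gk), c_r in zip(seg_nodes, c_r_list)
        ]
    )
    total = inflow.sum()
    if total <= 0:
        raise ValueError("no net uptake: check conductances and potentials")
    df = pd.DataFrame(seg_rows)
    df["inflow"] = inflow
    df["suf"] = inflow / total
    df["psi"] = [psi[gk] for _, gk in seg_nodes]
    krs = total / (psi_soil - psi_collar)
    return HydraulicSolution(
        segments=df,
        krs=float(krs),
        psi_soil=psi_soil,
        psi_collar=psi_collar,
        node_potentials=psi,
    )


# ---------------------------------------------------------------------------
# depth aggregation


DEFAULT_HORIZONS: tuple[tuple[float, float], ...] = (
    (0.0, 30.0),
    (30.0, 60.0),
    (60.0, 90.0),
    (90.0, 120.0),
)


def suf_profile(
    sol: HydraulicSolution,
    layer_thickness: float = 1.0,
    horizons: Sequence[tuple[float, float]] = DEFAULT_HORIZONS,
) -> tuple[pd.Series, pd.Series]:
    """Aggregate segment SUF per depth layer and per soil horizon.

    Segments are apportioned to bins by the same linear depth-clipping rule
    as the root-length depth profile, so refining the layer thickness never
    changes horizon aggregates.  Returns (per-layer Series indexed by layer
    top depth, per-horizon Series indexed by "lo-hi" labels; any SUF below
    the last horizon appears under "below").
    """
    df = sol.segments
    d0 = df["depth0"].to_numpy()
    d1 = df["depth1"].to_numpy()
    suf = df["suf"].to_numpy()
    layers = distribute_by_depth(d0, d1, suf, layer_thickness)

    labels = [f"{lo:g}-{hi:g}" for lo, hi in horizons]
    values = np.zeros(len(horizons))
    below = 0.0
    for a, b, v in zip(d0, d1, suf):
        lo, hi = (a, b) if a <= b else (b, a)
        span = hi - lo
        if span < 1e-12:
            placed = False
            for j, (hlo, hhi) in enumerate(horizons):
                if hlo <= lo < hhi:
                    values[j] += v
                    placed = True
                    break
            if not placed:
                below += v
            continue
        covered = 0.0
        for j, (hlo, hhi) in enumerate(horizons):
            ov = min(hi, hhi) - max(lo, hlo)
            if ov > 0:
                values[j] += v * ov / span
                covered += ov
        if span - covered > 1e-12:
            below += v * (span - covered) / span
    per_horizon = pd.Series(values, index=labels)
    if below > 1e-12:
        per_horizon["below"] = below
    return layers, per_horizon
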