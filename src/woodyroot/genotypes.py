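"""Genotype-specific growth and tropism parameter sets.

Ships the measured parameter tables for the three grapevine rootstock
genotypes "101-14", "SO4" and "R110" (estimated from 3-D digitized root
systems six months after planting), and YAML (de)serialization so the same
schema can be used as a config file.

Parameter semantics (per root type, types 2 and 3 grow dynamically):

* ``lmax`` (cm) — asymptotic root length of the negative-exponential law
* ``r`` (cm/day) — initial elongation rate
* ``lb``, ``la`` (cm, mean +/- SD) — basal and apical branch-free zones
  (type 2 only; type 3 bears no laterals)
* ``ln`` (cm, mean +/- SD) — interlateral distance
* ``theta`` (degrees, mean +/- SD) — insertion angle against the mother root
* ``a`` (cm, mean +/- SD) — root radius
* ``p_gravi`` — probability of gravitropic (vs. plagiotropic) growth
* ``N`` — tropism strength: number of candidate headings per growth step
* ``sigma`` — SD of the random angular change, per unit root length
  (rad per sqrt(cm) under the length-scaled random-walk convention)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

__all__ = ["Gaussian", "RootTypeParams", "GenotypeParams", "GENOTYPES", "load_params", "dump_params"]


@dataclass(frozen=True)
class Gaussian:
    """Mean/SD pair sampled from a normal truncated to positive values."""

    mean: float
    sd: float = 0.0

    def sample(self, rng: np.random.Generator, upper: Optional[float] = None) -> float:
        """Draw once, resampling until the value is positive (and below
        ``upper`` if given)."""
        if self.sd == 0:
            return self.mean
        hi = math.inf if upper is None else upper
        for _ in range(10_000):
            v = rng.normal(self.mean, self.sd)
            if 0.0 < v < hi:
                return float(v)
        raise RuntimeError(f"truncated sampling failed for N({self.mean}, {self.sd})")

    def truncated_mean(self, upper: Optional[float] = None) -> float:
        """Analytic mean of the positive-truncated normal (oracle for
        recovery tests)."""
        from scipy import stats

        if self.sd == 0:
            return self.mean
        a = (0.0 - self.mean) / self.sd
        b = math.inf if upper is None else (upper - self.mean) / self.sd
        return float(stats.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))


@dataclass
class RootTypeParams:
    lmax: float  # cm
    r: float  # cm / day
    theta: Gaussian  # degrees
    a: Gaussian  # cm
    p_gravi: float = 1.0
    N: int = 1
    sigma: float = 0.2  # rad per sqrt(cm)
    lb: Optional[Gaussian] = None  # cm
    la: Optional[Gaussian] = None  # cm
    ln: Optional[Gaussian] = None  # cm

    def __post_init__(self) -> None:
        if self.lmax <= 0 or self.r <= 0:
            raise ValueError("lmax and r must be positive")
        if not 0.0 <= self.p_gravi <= 1.0:
            raise ValueError("p_gravi must lie in [0, 1]")
        if self.N < 1:
            raise ValueError("tropism strength N must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.lb is not None and self.la is not None:
            if self.lb.mean + self.la.mean >= self.lmax:
                raise ValueError("lb.mean + la.mean must stay below lmax")


@dataclass
class GenotypeParams:
    """Full per-genotype parameter set driving the growth simulator."""

    name: str
    type2: RootTypeParams
    type3: RootTypeParams
    dx: float = 0.5  # cm, segment resolution
    emergence_time: float = 0.0  # days, type-2 emergence
    emergence_prob: float = 1.0
    tropism_mode: str = "per_segment"  # or "per_root"

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.tropism_mode not in ("per_segment", "per_root"):
            raise ValueError("tropism_mode must be 'per_segment' or 'per_root'")
        if not 0.0 <= self.emergence_prob <= 1.0:
            raise ValueError("emergence_prob must lie in [0, 1]")

    def for_type(self, root_type: int) -> RootTypeParams:
        if root_type == 2:
            return self.type2
        if root_type == 3:
            return self.type3
        raise KeyError(f"no dynamic parameters for root type {root_type}")


def _g(mean: float, sd: float = 0.0) -> Gaussian:
    return Gaussian(mean, sd)


#: Measured parameter tables per rootstock genotype (T2 excavation,
#: 6 months after planting).  Tropism: type 2 mixes gravitropic and
#: plagiotropic behaviour with genotype-specific probability; type 3 is
#: fixed gravitropic with N = 1.
GENOTYPES: dict[str, GenotypeParams] = {
    "101-14": GenotypeParams(
        name="101-14",
        type2=RootTypeParams(
            lmax=99.5, r=0.28,
            lb=_g(8.4, 6.2), la=_g(11.8, 8.3), ln=_g(4.1, 3.2),
            theta=_g(54.4, 20.6), a=_g(0.23, 0.04),
            p_gravi=0.85, N=2, sigma=0.2,
        ),
        type3=RootTypeParams(
            lmax=47.2, r=0.07,
            theta=_g(57.6, 21.9), a=_g(0.05, 0.02),
            p_gravi=1.0, N=1, sigma=0.2,
        ),
    ),
    "SO4": GenotypeParams(
        name="SO4",
        type2=RootTypeParams(
            lmax=89.9, r=0.29,
            lb=_g(7.8, 5.9), la=_g(16.4, 9.4), ln=_g(4.8, 3.5),
            theta=_g(51.8, 22.5), a=_g(0.20, 0.04),
            p_gravi=0.65, N=2, sigma=0.2,
        ),
        type3=RootTypeParams(
            lmax=66.7, r=0.08,
            theta=_g(50.4, 22.5), a=_g(0.05, 0.02),
            p_gravi=1.0, N=1, sigma=0.2,
        ),
    ),
    "R110": GenotypeParams(
        name="R110",
        type2=RootTypeParams(
            lmax=110.1, r=0.37,
            lb=_g(11.9, 10.6), la=_g(25.6, 16.9), ln=_g(6.7, 6.4),
            theta=_g(54.9, 23.0), a=_g(0.22, 0.03),
            p_gravi=0.95, N=2, sigma=0.2,
        ),
        type3=RootTypeParams(
            lmax=77.4, r=0.10,
            theta=_g(51.46, 22.5), a=_g(0.05, 0.02),
            p_gravi=1.0, N=1, sigma=0.2,
        ),
    ),
}


# ---------------------------------------------------------------------------
# YAML config round-trip


def _gauss_to_obj(g: Optional[Gaussian]):
    return None if g is None else {"mean": g.mean, "sd": g.sd}


def _obj_to_gauss(o) -> Optional[Gaussian]:
    if o is None:
        return None
    if isinstance(o, (int, float)):
        return Gaussian(float(o))
    return Gaussian(float(o["mean"]), float(o.get("sd", 0.0)))


def _type_to_obj(p: RootTypeParams) -> dict:
    return {
        "lmax": p.lmax, "r": p.r,
        "lb": _gauss_to_obj(p.lb), "la": _gauss_to_obj(p.la), "ln": _gauss_to_obj(p.ln),
        "theta": _gauss_to_obj(p.theta), "a": _gauss_to_obj(p.a),
        "p_gravi": p.p_gravi, "N": p.N, "sigma": p.sigma,
    }


def _obj_to_type(o: dict) -> RootTypeParams:
    return RootTypeParams(
        lmax=float(o["lmax"]), r=float(o["r"]),
        lb=_obj_to_gauss(o.get("lb")), la=_obj_to_gauss(o.get("la")),
        ln=_obj_to_gauss(o.get("ln")),
        theta=_obj_to_gauss(o["theta"]), a=_obj_to_gauss(o["a"]),
        p_gravi=float(o.get("p_gravi", 1.0)), N=int(o.get("N", 1)),
        sigma=float(o.get("sigma", 0.2)),
    )


def dump_params(params: GenotypeParams, destination=None) -> str:
    """Serialize a parameter set to YAML (path, stream, or returned string)."""
    obj = {
        "genotype": params.name,
        "dx": params.dx,
        "emergence_time": params.emergence_time,
        "emergence_prob": params.emergence_prob,
        "tropism_mode": params.tropism_mode,
        "type2": _type_to_obj(params.type2),
        "type3": _type_to_obj(params.type3),
    }
    text = yaml.safe_dump(obj, sort_keys=False)
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


def load_params(source) -> GenotypeParams:
    """Load a parameter set from a YAML path/stream, or by genotype name."""
    if isinstance(source, str) and source in GENOTYPES:
        return GENOTYPES[source]
    if hasattr(source, "read"):
        obj = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            obj = yaml.safe_load(fh)
    return GenotypeParams(
        name=str(obj.get("genotype", "custom")),
        type2=_obj_to_type(obj["type2"]),
        type3=_obj_to_type(obj["type3"]),
        dx=float(obj.get("dx", 0.5)),
        emergence_time=float(obj.get("emergence_time", 0.0)),
        emergence_prob=float(obj.get("emergence_prob", 1.0)),
        tropism_mode=str(obj.get("tropism_mode", "per_segment")),
    )
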