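import io

import numpy as np
import pytest

from woodyroot import GENOTYPES, Axis, RootSystem, build_root_system, parse_points
from woodyroot.growth_sim import initialize_static, simulate
from woodyroot.synthetic_fixtures import make_static_template

# Hand-written digitizer file: stem with 4 points (grafting, soil horizon,
# two basal), one type-1 axis with 3 points off stem point 2, one type-2
# axis with 2 points off point 2 of that axis.  Coordinates are in the
# digitizer frame: (x_d, y_d, z_d) -> soil (y_d, z_d, -x_d); x_d is depth
# positive-down shifted so that stem point 1 maps to the soil surface.
TOY_DIGITIZER = """\
# toy plant
# soil_ref=1
0 stem 35.0 10.0 20.0
1 stem 50.0 10.0 20.0
2 stem 68.0 10.0 20.0
3 stem 70.0 10.0 20.0
2.1 root 68.0 10.0 20.0
2.2 root 70.0 16.0 20.0
2.3 root 72.0 22.0 20.0
2.2.1 root 70.1 16.0 20.0
2.2.2 root 75.0 16.0 24.0
"""


@pytest.fixture()
def toy_text() -> str:
    return TOY_DIGITIZER


@pytest.fixture()
def toy_system():
    records = parse_points(io.StringIO(TOY_DIGITIZER))
    rs, deviations = build_root_system(records, soil_ref=(1,))
    return rs, deviations


def straight_system(
    stem_len: float = 10.0,
    root_len: float = 50.0,
    n_seg: int = 10,
    radius: float = 0.05,
    root_age: float = 100.0,
) -> RootSystem:
    """Stem plus a single straight vertical type-1 root, n_seg segments."""
    rs = RootSystem()
    stem_nodes = np.array([[0.0, 0.0, stem_len], [0.0, 0.0, 0.0]])
    rs.add_axis(Axis(axis_id=(), nodes=stem_nodes, root_type=0, radius=0.5))
    z = -np.linspace(0.0, root_len, n_seg + 1)
    nodes = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    rs.add_axis(
        Axis(
            axis_id=(1,),
            nodes=nodes,
            root_type=1,
            radius=radius,
            node_ages=np.full(n_seg + 1, root_age),
            parent=(),
            parent_node=1,
        )
    )
    rs.validate()
    return rs


@pytest.fixture()
def vertical_root():
    return straight_system()


@pytest.fixture(scope="session")
def sim_180():
    """One 180-day simulation of the default genotype on the default template."""
    template = make_static_template(seed=5)
    state = initialize_static(template, GENOTYPES["101-14"])
    return simulate(state, days=180.0, seed=5)
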