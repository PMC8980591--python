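import numpy as np
import pytest

from pericav.geometry import QuadMesh, GeometryParams, build_paired_geometry
from pericav.materials import SolidMaterialParams


def make_single_square(h=1e-3):
    """One unit-material square element of side h."""
    nodes = np.array([[0, 0], [h, 0], [h, h], [0, h]], dtype=float)
    return QuadMesh(nodes, np.array([[0, 1, 2, 3]]),
                    np.array([""], dtype=object),
                    np.array(["brain"], dtype=object), {})


def make_patch(n=4, h=1e-3):
    """Structured (n-1)x(n-1) patch of square elements of side h."""
    xs, ys = np.meshgrid(np.linspace(0, (n - 1) * h, n),
                         np.linspace(0, (n - 1) * h, n), indexing="ij")
    nodes = np.column_stack([xs.ravel(), ys.ravel()])
    conn = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            conn.append([a, a + n, a + n + 1, a + 1])
    E = len(conn)
    return QuadMesh(nodes, np.array(conn), np.full(E, "", dtype=object),
                    np.full(E, "brain", dtype=object), {})


@pytest.fixture(scope="session")
def default_pair():
    """The default paired geometries (built once per session)."""
    return build_paired_geometry(GeometryParams())


@pytest.fixture(scope="session")
def measured_sound_speed():
    """Front speed of a small disturbance in the reference 1D column."""
    from pericav.fluid import measure_sound_speed

    return measure_sound_speed(n_cells=800)


@pytest.fixture(scope="session")
def demo_experiment():
    """The single-case paired demo experiment (several minutes; shared)."""
    from pericav.pipeline import demo_config, run_paired_experiment

    return run_paired_experiment(demo_config())


@pytest.fixture
def brain():
    return SolidMaterialParams()
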