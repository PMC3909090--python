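"""Shared fixtures: the synthetic knob-pocket system and its surface pipeline.

The expensive stages (surface generation, classification, triangle building)
run once per session; tests treat the results as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from hopdock.conservation import annotate_critical_points
from hopdock.fixtures import make_knob_pocket_pair
from hopdock.surface import classify_critical_points, generate_surface_points
from hopdock.triangles import build_active_triangles


@pytest.fixture(scope="session")
def system():
    """The default synthetic knob-pocket dimer (seed 0)."""
    return make_knob_pocket_pair(seed=0)


@pytest.fixture(scope="session")
def charged_system():
    """Knob-pocket dimer with the charge ring and H-bond caps enabled."""
    return make_knob_pocket_pair(seed=0, charged_ring=True, hbond_caps=True)


@pytest.fixture(scope="session")
def dense_surfaces(system):
    return (
        generate_surface_points(system.unit_a),
        generate_surface_points(system.unit_b),
    )


@pytest.fixture(scope="session")
def critical_points(system, dense_surfaces):
    dense_a, dense_b = dense_surfaces
    return (
        classify_critical_points(dense_a, system.unit_a),
        classify_critical_points(dense_b, system.unit_b),
    )


@pytest.fixture(scope="session")
def annotated_points(system, critical_points):
    points_a, points_b = critical_points
    annotate_critical_points(points_a, system.scores_a)
    annotate_critical_points(points_b, system.scores_b)
    return points_a, points_b


@pytest.fixture(scope="session")
def triangle_lists(annotated_points):
    points_a, points_b = annotated_points
    return build_active_triangles(points_a), build_active_triangles(points_b)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


PDB_4ATOM = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.935  1.00  0.00           C
ATOM      4  O   ALA A   1      13.405   7.533  -5.866  1.00  0.00           O
TER
END
"""


@pytest.fixture()
def four_atom_pdb(tmp_path):
    path = tmp_path / "four.pdb"
    path.write_text(PDB_4ATOM)
    return path
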