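"""Shared fixtures: analytic meshes and small reference trees.

Everything is generated programmatically — no binary fixture files.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from paleodiv import SimulationConfig, parse_tree, simulate_fbd_tree


def uv_hemisphere(radius: float = 1.0, n_theta: int = 100, n_phi: int = 50) -> trimesh.Trimesh:
    """Upper hemisphere on a latitude/longitude grid with a clean equator rim.

    3D area -> 2*pi*r^2 and occlusal outline area -> pi*r^2 as the grid is
    refined, so RFI -> ln(sqrt(2)).  Default resolution: 9,900 faces.
    """
    verts = [(0.0, 0.0, radius)]
    faces = []
    for i in range(1, n_phi + 1):
        phi = (np.pi / 2) * i / n_phi
        for j in range(n_theta):
            th = 2 * np.pi * j / n_theta
            verts.append(
                (radius * np.sin(phi) * np.cos(th), radius * np.sin(phi) * np.sin(th), radius * np.cos(phi))
            )

    def idx(i, j):
        return 1 + (i - 1) * n_theta + (j % n_theta)

    for j in range(n_theta):
        faces.append([0, idx(1, j), idx(1, j + 1)])
    for i in range(1, n_phi):
        for j in range(n_theta):
            a, b, c, d = idx(i, j), idx(i, j + 1), idx(i + 1, j + 1), idx(i + 1, j)
            faces.append([a, b, c])
            faces.append([a, c, d])
    return trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)


def four_sided_pyramid(rot_deg: float = 10.0) -> trimesh.Trimesh:
    """Square pyramid, each side split into 3 coplanar triangles.

    The four side normals have azimuths 90 degrees apart, offset ``rot_deg``
    from the axes so no normal sits on an azimuth-bin boundary under any of
    the 8 OPCR rotations.
    """
    th = np.radians(rot_deg + np.array([45.0, 135.0, 225.0, 315.0]))
    base = [np.array([np.sqrt(2) * np.cos(t), np.sqrt(2) * np.sin(t), 0.0]) for t in th]
    apex = np.array([0.0, 0.0, 1.0])
    verts = [apex] + base
    faces = []
    for i in range(4):
        b1, b2 = base[i], base[(i + 1) % 4]
        cen = (apex + b1 + b2) / 3.0
        ci = len(verts)
        verts.append(cen)
        faces += [[0, 1 + i, ci], [1 + i, 1 + (i + 1) % 4, ci], [0, ci, 1 + (i + 1) % 4]]
    return trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)


def tilted_plane(face_count: int = 400, slope: float = 0.3) -> trimesh.Trimesh:
    from paleodiv import generate_tooth_mesh

    flat = generate_tooth_mesh(n_cusps=0, relief=0.0, face_count=face_count)
    v = flat.vertices.copy()
    v[:, 2] += slope * v[:, 0]
    return trimesh.Trimesh(vertices=v, faces=flat.faces, process=False)


@pytest.fixture(scope="session")
def hemisphere():
    return uv_hemisphere()


@pytest.fixture(scope="session")
def pyramid():
    return four_sided_pyramid()


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); with root age 2: all tips extant."""
    return parse_tree("((A:1,B:1):1,C:2);", root_age=2)


@pytest.fixture(scope="session")
def fossil_trees():
    """Ten small fossil birth-death trees for oracle cross-checks."""
    out = []
    for seed in range(10):
        cfg = SimulationConfig(
            seed=seed, birth_rate=0.15, death_rate=0.08, fossil_rate=0.1,
            root_age=40.0, min_tips=8, max_tips=60,
        )
        out.append(simulate_fbd_tree(cfg, max_retries=2000))
    return out
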