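import numpy as np
import pytest

from arthropose.surface import TriMesh


def icosphere(subdiv: int = 3, radius: float = 1.0) -> TriMesh:
    """Subdivided icosahedron with vertices projected to the exact sphere."""
    t = (1 + 5**0.5) / 2
    verts = np.array(
        [[-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
         [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
         [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], float)
    faces = [[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
             [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
             [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
             [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]]
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdiv):
        mid: dict = {}
        vl = [v for v in verts]
        newf = []

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in mid:
                p = (vl[a] + vl[b]) / 2
                vl.append(p / np.linalg.norm(p))
                mid[key] = len(vl) - 1
            return mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            newf += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = newf
        verts = np.array(vl)
    return TriMesh(verts * radius, np.array(faces, np.int64))


def cylinder_grid(radius: float = 2.0, length: float = 10.0,
                  ncirc: int = 200, nax: int = 20) -> TriMesh:
    """Closed-loop axial strip mesh of a cylinder along z (open ends)."""
    th = np.linspace(0, 2 * np.pi, ncirc, endpoint=False)
    z = np.linspace(0, length, nax)
    verts = np.array([[radius * np.cos(t), radius * np.sin(t), zz]
                      for zz in z for t in th])
    faces = []
    for j in range(nax - 1):
        for i in range(ncirc):
            a = j * ncirc + i
            b = j * ncirc + (i + 1) % ncirc
            c = (j + 1) * ncirc + (i + 1) % ncirc
            d = (j + 1) * ncirc + i
            faces += [[a, b, c], [a, c, d]]
    return TriMesh(verts, np.array(faces, np.int64))


@pytest.fixture(scope="session")
def unit_icosphere():
    return icosphere(4)


@pytest.fixture(scope="session")
def sphere_knee():
    from arthropose.synthetic_fixtures import make_sphere_knee

    return make_sphere_knee(R=20.0, edge=1.0)


@pytest.fixture(scope="session")
def cylinder_knee():
    from arthropose.synthetic_fixtures import make_cylinder_knee

    return make_cylinder_knee(R=20.0, length=40.0, edge=1.0)


@pytest.fixture(scope="session")
def tube_capsule():
    from arthropose.synthetic_fixtures import make_tube_capsule

    return make_tube_capsule()


@pytest.fixture(scope="session")
def toy_limb():
    from arthropose.synthetic_fixtures import make_toy_limb

    return make_toy_limb()
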