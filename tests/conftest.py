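import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def winding_number(points, X, faces, chunk=200):
    """Generalized winding number of ``points`` w.r.t. a closed mesh
    (van Oosterom–Strackee solid angles); ~1 inside, ~0 outside.

    Independent containment oracle: shares no code with the package's
    ray-casting machinery.
    """
    out = np.zeros(len(points))
    tri = X[faces]
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        a = tri[None, :, 0] - p[:, None]
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("rti,rti->rt", a, np.cross(b, c))
        den = (la * lb * lc
               + np.einsum("rti,rti->rt", a, b) * lc
               + np.einsum("rti,rti->rt", b, c) * la
               + np.einsum("rti,rti->rt", c, a) * lb)
        out[s:s + chunk] = np.arctan2(num, den).sum(axis=1) / (2 * np.pi)
    return out


def finite_difference_gradient(mesh, energy_fn, eps=1e-7):
    """Central-difference gradient of a mesh energy functional."""
    g = np.zeros_like(mesh.X)
    for i in range(mesh.n_vertices):
        for d in range(3):
            mesh.X[i, d] += eps
            ep = energy_fn(mesh)
            mesh.X[i, d] -= 2 * eps
            em = energy_fn(mesh)
            mesh.X[i, d] += eps
            g[i, d] = (ep - em) / (2 * eps)
    return g
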