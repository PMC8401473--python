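"""Independent small-strain linear-elastic hexahedral solver.

Test oracle for the small-gravity limit of the nonlinear solver: standard
engineering linear elasticity assembled from the isotropic stiffness
tensor, with the volumetric part of the strain integrated at the element
centre (selective reduced integration) so the oracle does not lock at
nu = 0.49 either.  Deliberately shares no code with the package solver:
dense per-element loops, direct sparse solve.
"""

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

_CORN = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                  [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)
_GP = [(np.array([sx, sy, sz]) / np.sqrt(3.0), 1.0)
       for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]


def _dN(xi):
    t = 1.0 + _CORN * xi
    out = np.empty((8, 3))
    out[:, 0] = _CORN[:, 0] * t[:, 1] * t[:, 2]
    out[:, 1] = _CORN[:, 1] * t[:, 0] * t[:, 2]
    out[:, 2] = _CORN[:, 2] * t[:, 0] * t[:, 1]
    return out / 8.0


def _shape_vals(xi):
    return np.prod(1.0 + _CORN * xi, axis=1) / 8.0


def _bmat(grad):
    """6x24 engineering strain-displacement matrix."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def solve_linear_gravity(nodes, elements, E_per_elem, nu, rho_per_elem,
                         gravity, fixed):
    """Nodal displacements of the linear-elastic gravity problem.

    Parameters mirror the package's mesh/BC structures but are plain
    arrays; ``fixed`` is an (N, 3) boolean mask.  Units: mm, kPa, kg/m^3,
    m/s^2.
    """
    nodes = np.asarray(nodes, float)
    elements = np.asarray(elements)
    n = len(nodes)
    ndof = 3 * n
    rows, cols, vals = [], [], []
    f = np.zeros(ndof)
    # deviatoric / volumetric split of the isotropic stiffness
    Idev = np.diag([1, 1, 1, 0.5, 0.5, 0.5]).astype(float)
    vvec = np.array([1.0, 1.0, 1.0, 0, 0, 0])
    for e, conn in enumerate(elements):
        X = nodes[conn]
        mu = E_per_elem[e] / (2 * (1 + nu))
        K = E_per_elem[e] / (3 * (1 - 2 * nu))
        Cdev = 2 * mu * (Idev - np.outer(vvec, vvec) / 3.0)
        Cvol = K * np.outer(vvec, vvec)
        Ke = np.zeros((24, 24))
        fe = np.zeros(24)
        b = rho_per_elem[e] * 1e-6 * np.asarray(gravity, float)
        for xi, w in _GP:
            J = X.T @ _dN(xi)
            det = np.linalg.det(J)
            grad = _dN(xi) @ np.linalg.inv(J)
            B = _bmat(grad)
            Ke += w * det * B.T @ Cdev @ B
            Nv = _shape_vals(xi)
            for a in range(8):
                fe[3 * a:3 * a + 3] += w * det * Nv[a] * b
        # volumetric part at the centre point
        J = X.T @ _dN(np.zeros(3))
        det = np.linalg.det(J)
        grad = _dN(np.zeros(3)) @ np.linalg.inv(J)
        B = _bmat(grad)
        Ke += 8.0 * det * B.T @ Cvol @ B
        dof = np.array([3 * c + k for c in conn for k in range(3)])
        rows.append(np.repeat(dof, 24))
        cols.append(np.tile(dof, 24))
        vals.append(Ke.ravel())
        f[dof] += fe
    A = sp.coo_array((np.concatenate(vals),
                      (np.concatenate(rows), np.concatenate(cols))),
                     shape=(ndof, ndof)).tocsr()
    free = ~np.asarray(fixed, bool).reshape(-1)
    u = np.zeros(ndof)
    Aff = A[free][:, free].tocsc()
    u[free] = spla.spsolve(Aff, f[free])
    return u.reshape(-1, 3)
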