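"""Linear (P1) finite-element assembly on the simulator's meshes.

Internal module.  All operators are assembled with piecewise-linear basis
functions.  For axisymmetric meshes every integral carries the cylindrical
weight ``r`` and is taken per radian; physical (revolved) quantities are
obtained by multiplying by ``2*pi``, which the calling modules do only in
user-facing integrals (volumes, mass budgets) since the factor cancels
inside linear systems.

The moment formulas used here are exact for linear basis functions:
``int phi_i r dA = A (2 r_i + r_j + r_k) / 12`` on a triangle, and the
classical ``V/10 - V/20`` mass matrix on a tetrahedron.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import Mesh


class P1Basis:
    """Precomputed per-cell P1 data: gradients, measures, lumped weights."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        dim = mesh.dim
        verts = mesh.points[mesh.cells]  # (M, nv, dim)
        nv = dim + 1
        # gradients: solve [1 x] a = e_i per cell
        mats = np.concatenate([np.ones((len(verts), nv, 1)), verts], axis=2)
        inv = np.linalg.inv(mats)  # (M, nv, nv); rows: [const, grad...]
        self.grads = np.transpose(inv[:, 1:, :], (0, 2, 1))  # (M, nv, dim)
        if dim == 2:
            e1 = verts[:, 1] - verts[:, 0]
            e2 = verts[:, 2] - verts[:, 0]
            self.plane_measure = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
            r = verts[:, :, 0]
            self.measure = self.plane_measure * r.mean(axis=1)  # int r dA (per radian)
            # int phi_i r dA
            self.lump = self.plane_measure[:, None] * (r + r.sum(axis=1, keepdims=True)) / 12.0
            # int phi_i phi_j r dA
            A = self.plane_measure
            M = np.empty((len(A), 3, 3))
            for i in range(3):
                for j in range(3):
                    if i == j:
                        others = [k for k in range(3) if k != i]
                        M[:, i, i] = A * (r[:, i] / 10.0 + r[:, others].sum(axis=1) / 30.0)
                    else:
                        k = 3 - i - j
                        M[:, i, j] = A * ((r[:, i] + r[:, j]) / 30.0 + r[:, k] / 60.0)
            self.mass_local = M
        else:
            self.plane_measure = mesh.cell_volumes
            self.measure = mesh.cell_volumes
            self.lump = np.broadcast_to(self.measure[:, None] / 4.0, (len(verts), 4)).copy()
            V = self.measure
            M = np.full((len(V), 4, 4), 1.0 / 20.0) * V[:, None, None]
            M[:, np.arange(4), np.arange(4)] = V[:, None] / 10.0
            self.mass_local = M
        self.nv = nv
        rows = np.repeat(mesh.cells, nv, axis=1)  # (M, nv*nv)
        cols = np.tile(mesh.cells, (1, nv))
        self._rows = rows.ravel()
        self._cols = cols.ravel()

    def assemble(self, local: np.ndarray) -> sp.csr_matrix:
        """Assemble (M, nv, nv) local matrices into a global CSR matrix."""
        n = self.mesh.n_points
        K = sp.coo_matrix((local.reshape(len(local), -1).ravel(), (self._rows, self._cols)), shape=(n, n))
        return K.tocsr()

    def stiffness(self, coeff: np.ndarray) -> sp.csr_matrix:
        """int coeff * grad(phi_i) . grad(phi_j), coeff per cell."""
        gg = np.einsum("eid,ejd->eij", self.grads, self.grads)
        return self.assemble(gg * (coeff * self.measure)[:, None, None])

    def mass(self, coeff: np.ndarray | float = 1.0) -> sp.csr_matrix:
        coeff = np.broadcast_to(np.asarray(coeff, dtype=float), (len(self.mesh.cells),))
        return self.assemble(self.mass_local * coeff[:, None, None])

    def lumped_mass(self, coeff: np.ndarray | float = 1.0) -> np.ndarray:
        """Diagonal of the row-lumped weighted mass matrix (length n_points)."""
        coeff = np.broadcast_to(np.asarray(coeff, dtype=float), (len(self.mesh.cells),))
        diag = np.zeros(self.mesh.n_points)
        np.add.at(diag, self.mesh.cells, self.lump * coeff[:, None])
        return diag

    def convection(self, u_cell: np.ndarray) -> sp.csr_matrix:
        """Conservative convection: B_ij = -int (u . grad phi_i) phi_j.

        Together with the boundary outflow operator this is the weak form
        of div(C u); global column sums vanish, so it creates or destroys
        no mass in the interior.
        """
        udotg = np.einsum("ed,eid->ei", u_cell, self.grads)  # (M, nv)
        local = -udotg[:, :, None] * self.lump[:, None, :]
        return self.assemble(local)

    def streamline_diffusion(
        self, u_cell: np.ndarray, D_cell: np.ndarray, crosswind: float = 0.35
    ) -> sp.csr_matrix:
        """Convection stabilization for the high-Peclet regime.

        Three ingredients, each targeting a distinct failure mode of plain
        Galerkin at high cell Peclet number:

        * streamline (SUPG-type) term tau (u.grad phi_i)(u.grad phi_j)
          with the optimal tau = h/(2|u|) (coth Pe - 1/Pe);
        * a small crosswind artificial diffusion
          ``crosswind * max(0, |u| h / 2 - D)`` acting only perpendicular
          to the flow, which suppresses lateral oscillations streamline
          stabilization cannot reach while leaving transport along
          streamlines untouched;
        * full (isotropic) upwind diffusion restricted to the one-cell
          band around the tumor/healthy interface, where the jump in
          hydraulic conductivity kinks the velocity field and compresses
          fronts that the smooth-coefficient stabilizations miss.
        """
        unorm = np.linalg.norm(u_cell, axis=1)
        if self.mesh.dim == 2:
            h = np.sqrt(2.0 * self.plane_measure)
        else:
            h = (6.0 * self.measure) ** (1.0 / 3.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Pe = unorm * h / (2.0 * np.maximum(D_cell, 1e-300))
            xi = 1.0 / np.tanh(np.clip(Pe, 1e-12, 7e2)) - 1.0 / np.clip(Pe, 1e-12, None)
            tau = np.where(unorm > 0, h / (2.0 * np.maximum(unorm, 1e-300)) * xi, 0.0)
        udotg = np.einsum("ed,eid->ei", u_cell, self.grads)
        local = tau[:, None, None] * udotg[:, :, None] * udotg[:, None, :] * self.measure[:, None, None]
        if crosswind > 0.0:
            nu = crosswind * np.maximum(0.0, 0.5 * unorm * h - D_cell)
            s = np.where(unorm[:, None] > 0, u_cell / np.maximum(unorm, 1e-300)[:, None], 0.0)
            gg = np.einsum("eid,ejd->eij", self.grads, self.grads)
            gs = np.einsum("eid,ed->ei", self.grads, s)
            local = local + (nu * self.measure)[:, None, None] * (gg - gs[:, :, None] * gs[:, None, :])
        S = self.assemble(local)
        frac = self.mesh.tumor_fraction
        cut = (frac > 0.0) & (frac < 1.0)
        if cut.any():
            band_nodes = np.zeros(self.mesh.n_points, dtype=bool)
            band_nodes[np.unique(self.mesh.cells[cut])] = True
            band = band_nodes[self.mesh.cells].any(axis=1)
            nu_iso = np.where(band, np.maximum(0.0, 0.5 * unorm * h - D_cell), 0.0)
            S = S + self.stiffness(nu_iso)
        return S


class BoundaryGroup:
    """Boundary facets of one tag with adjacency and outward normals."""

    def __init__(self, mesh: Mesh, tag: int, basis: P1Basis):
        self.mesh = mesh
        facets = mesh.facets_by_tag(tag)
        self.facets = facets
        if len(facets) == 0:
            self.cell_index = np.zeros(0, dtype=np.int64)
            self.normals = np.zeros((0, mesh.dim))
            self.weights = np.zeros((0, mesh.dim))
            return
        # adjacent cell: match each boundary facet against all cell facets
        if mesh.dim == 2:
            local = [(0, 1), (1, 2), (2, 0)]
        else:
            local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
        all_facets = np.vstack([mesh.cells[:, f] for f in local])
        owner = np.tile(np.arange(len(mesh.cells)), len(local))
        key = np.sort(all_facets, axis=1)
        order = np.lexsort(key.T[::-1])
        key_sorted = key[order]
        query = np.sort(facets, axis=1)
        # binary search on lexicographically sorted rows
        idx = np.searchsorted(
            key_sorted.view([("", key.dtype)] * key.shape[1]).ravel(),
            query.view([("", query.dtype)] * query.shape[1]).ravel(),
        )
        self.cell_index = owner[order[idx]]

        fp = mesh.points[facets]
        cen_cells = mesh.points[mesh.cells[self.cell_index]].mean(axis=1)
        if mesh.dim == 2:
            t = fp[:, 1] - fp[:, 0]
            self.length = np.linalg.norm(t, axis=1)
            n = np.column_stack([t[:, 1], -t[:, 0]]) / self.length[:, None]
            # int phi_i r ds on each edge
            r = fp[:, :, 0]
            self.weights = self.length[:, None] * (r + r.sum(axis=1, keepdims=True)) / 6.0
            # int phi_i phi_j r ds
            L = self.length
            m = np.empty((len(facets), 2, 2))
            m[:, 0, 0] = L * (3 * r[:, 0] + r[:, 1]) / 12.0
            m[:, 1, 1] = L * (r[:, 0] + 3 * r[:, 1]) / 12.0
            m[:, 0, 1] = m[:, 1, 0] = L * (r[:, 0] + r[:, 1]) / 12.0
            self.mass_local = m
        else:
            e1 = fp[:, 1] - fp[:, 0]
            e2 = fp[:, 2] - fp[:, 0]
            cr = np.cross(e1, e2)
            area = 0.5 * np.linalg.norm(cr, axis=1)
            self.length = area
            n = cr / (2.0 * area)[:, None]
            self.weights = np.broadcast_to(area[:, None] / 3.0, (len(facets), 3)).copy()
            m = np.full((len(facets), 3, 3), 1.0 / 12.0) * area[:, None, None]
            m[:, np.arange(3), np.arange(3)] = area[:, None] / 6.0
            self.mass_local = m
        # orient outward (away from adjacent cell centroid)
        to_face = fp.mean(axis=1) - cen_cells
        flip = np.einsum("fd,fd->f", n, to_face) < 0
        n[flip] *= -1.0
        self.normals = n

    @property
    def total_weight(self) -> float:
        """int r ds (axisymmetric, per radian) or total area (3D)."""
        return float(self.weights.sum())

    def load_vector(self, n_points: int, value: float = 1.0) -> np.ndarray:
        """Assemble int value * phi_i over the group into a global vector."""
        f = np.zeros(n_points)
        if len(self.facets):
            np.add.at(f, self.facets, value * self.weights)
        return f

    def outflow_matrix(self, u_cell: np.ndarray, n_points: int) -> sp.csr_matrix:
        """int phi_i phi_j max(u.n, 0) over the group (advective outflow)."""
        if len(self.facets) == 0:
            return sp.csr_matrix((n_points, n_points))
        un = np.einsum("fd,fd->f", u_cell[self.cell_index], self.normals)
        un = np.maximum(un, 0.0)
        local = self.mass_local * un[:, None, None]
        nv = self.facets.shape[1]
        rows = np.repeat(self.facets, nv, axis=1).ravel()
        cols = np.tile(self.facets, (1, nv)).ravel()
        return sp.coo_matrix((local.reshape(len(local), -1).ravel(), (rows, cols)), shape=(n_points, n_points)).tocsr()

    def flux(self, u_cell: np.ndarray, values: np.ndarray | None = None) -> float:
        """int (values) u.n over the group (per radian in axisymmetric)."""
        if len(self.facets) == 0:
            return 0.0
        un = np.einsum("fd,fd->f", u_cell[self.cell_index], self.normals)
        if values is None:
            return float((un * self.weights.sum(axis=1)).sum())
        vals = values[self.facets]
        return float((un * (vals * self.weights).sum(axis=1)).sum())


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, nodes: np.ndarray, value: float | np.ndarray):
    """Symmetric Dirichlet elimination: returns modified copies of (A, b).

    Constrained rows and columns are zeroed (their contribution moved to
    the right-hand side), so a symmetric operator stays symmetric and
    Krylov solvers for SPD systems remain applicable.
    """
    n = A.shape[0]
    vals = np.zeros(n)
    vals[nodes] = value
    free = np.ones(n)
    free[nodes] = 0.0
    A = A.tocsr()
    b = free * (b - A @ vals) + vals
    P = sp.diags(free)
    A = P @ A @ P + sp.diags(1.0 - free)
    return A.tocsr(), b
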