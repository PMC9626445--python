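"""Tetrahedral mesh container with the P1 finite-element geometry caches.

Holds reference-configuration points and cells plus the quantities every
assembly loop needs: cell volumes, constant P1 shape-function gradients,
barycentres and the boundary (faces shared by exactly one cell).  Lengths in
mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TetMesh:
    points: np.ndarray  # (N, 3)
    cells: np.ndarray   # (M, 4) int

    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if self.cells.ndim != 2 or self.cells.shape[1] != 4:
            raise ValueError("cells must have shape (M, 4)")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    @property
    def cell_points(self) -> np.ndarray:
        if "cell_points" not in self._cache:
            self._cache["cell_points"] = self.points[self.cells]  # (M, 4, 3)
        return self._cache["cell_points"]

    @property
    def signed_volumes(self) -> np.ndarray:
        if "svol" not in self._cache:
            X = self.cell_points
            e = X[:, 1:] - X[:, :1]
            self._cache["svol"] = np.einsum(
                "mi,mi->m", e[:, 0], np.cross(e[:, 1], e[:, 2])) / 6.0
        return self._cache["svol"]

    @property
    def volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes)

    @property
    def barycenters(self) -> np.ndarray:
        if "bary" not in self._cache:
            self._cache["bary"] = self.cell_points.mean(axis=1)
        return self._cache["bary"]

    @property
    def grad_phi(self) -> np.ndarray:
        """Constant gradients of the 4 P1 shape functions per cell, (M, 4, 3)."""
        if "grad" not in self._cache:
            X = self.cell_points
            A = np.concatenate([np.ones((self.n_cells, 4, 1)), X], axis=2)  # (M,4,4)
            Ainv = np.linalg.inv(A)
            self._cache["grad"] = np.swapaxes(Ainv[:, 1:, :], 1, 2)  # (M,4,3)
        return self._cache["grad"]

    @property
    def boundary_faces(self) -> np.ndarray:
        """Triangles shared by exactly one tetrahedron, (F, 3) node indices."""
        if "bfaces" not in self._cache:
            c = self.cells
            faces = np.concatenate([c[:, [0, 1, 2]], c[:, [0, 1, 3]],
                                    c[:, [0, 2, 3]], c[:, [1, 2, 3]]])
            key = np.sort(faces, axis=1)
            _, idx, counts = np.unique(key, axis=0, return_index=True,
                                       return_counts=True)
            self._cache["bfaces"] = faces[idx[counts == 1]]
        return self._cache["bfaces"]

    @property
    def boundary_nodes(self) -> np.ndarray:
        if "bnodes" not in self._cache:
            self._cache["bnodes"] = np.unique(self.boundary_faces)
        return self._cache["bnodes"]

    @property
    def edge_lengths(self) -> np.ndarray:
        """All six edge lengths per cell, (M, 6)."""
        if "edges" not in self._cache:
            X = self.cell_points
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
            self._cache["edges"] = np.stack(
                [np.linalg.norm(X[:, a] - X[:, b], axis=1) for a, b in pairs],
                axis=1)
        return self._cache["edges"]

    @property
    def cell_sizes(self) -> np.ndarray:
        """Characteristic size per cell (max edge length), (M,)."""
        return self.edge_lengths.max(axis=1)

    def aspect_ratios(self) -> np.ndarray:
        """Circumradius over (3 x inradius) per cell; 1 for a regular tetrahedron."""
        X = self.cell_points
        V = self.volumes
        # face areas opposite each vertex
        areas = np.empty((self.n_cells, 4))
        for k, (a, b, c) in enumerate([(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]):
            areas[:, k] = 0.5 * np.linalg.norm(
                np.cross(X[:, b] - X[:, a], X[:, c] - X[:, a]), axis=1)
        r_in = 3.0 * V / areas.sum(axis=1)
        # circumradius via the Cayley-Menger-free formula R = |detM| route:
        # solve for circumcentre from |x - Xi|^2 equal for all i
        A = 2.0 * (X[:, 1:] - X[:, :1])
        b = np.einsum("mij,mij->mi", X[:, 1:], X[:, 1:]) - np.einsum(
            "mj,mj->m", X[:, 0], X[:, 0])[:, None]
        centre = np.linalg.solve(A, b[..., None])[..., 0]
        R = np.linalg.norm(centre - X[:, 0], axis=1)
        return R / (3.0 * r_in)

    def validate(self) -> None:
        """Raise on inverted or degenerate cells, naming the first offender."""
        sv = self.signed_volumes
        bad = np.nonzero(sv <= 0.0)[0]
        if bad.size:
            raise ValueError(f"cell {int(bad[0])} has non-positive signed volume "
                             f"({sv[bad[0]]:.3e} mm^3): inverted or degenerate")

    def orient(self) -> "TetMesh":
        """Return a copy with all cells reordered to positive signed volume."""
        sv = self.signed_volumes
        cells = self.cells.copy()
        flip = sv < 0.0
        cells[flip] = cells[flip][:, [0, 1, 3, 2]]
        return TetMesh(points=self.points.copy(), cells=cells)

    def point_gradient(self, nodal: np.ndarray) -> np.ndarray:
        """Material gradient per cell of a P1 nodal field.

        nodal (N,) -> (M, 3); nodal (N, d) -> (M, d, 3).
        """
        vals = np.asarray(nodal, dtype=float)[self.cells]  # (M, 4) or (M, 4, d)
        if vals.ndim == 2:
            return np.einsum("ma,mai->mi", vals, self.grad_phi)
        return np.einsum("mad,mai->mdi", vals, self.grad_phi)

    def cell_mean(self, nodal: np.ndarray) -> np.ndarray:
        """Barycentre value per cell of a P1 nodal field."""
        return np.asarray(nodal, dtype=float)[self.cells].mean(axis=1)

    def find_cells(self, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Cell index containing each query point (-1 if outside the mesh)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        from scipy.spatial import cKDTree

        tree = self._cache.get("btree")
        if tree is None:
            tree = cKDTree(self.barycenters)
            self._cache["btree"] = tree
        k = min(32, self.n_cells)
        _, cand = tree.query(pts, k=k)
        cand = np.atleast_2d(cand)
        out = np.full(pts.shape[0], -1, dtype=int)
        for i, p in enumerate(pts):
            for c in cand[i]:
                if self._inside(int(c), p, tol):
                    out[i] = int(c)
                    break
            else:
                # brute-force fallback for points missed by the kd-tree heuristic
                lam = self._barycentric_all(p)
                ok = np.nonzero(np.all(lam >= -tol, axis=1))[0]
                if ok.size:
                    out[i] = int(ok[0])
        return out

    def _barycentric_all(self, p: np.ndarray) -> np.ndarray:
        G = self.grad_phi  # (M, 4, 3)
        bary = self.cell_points[:, 0]  # use shape functions directly
        # P1 shape function a evaluated at p: phi_a(p) = phi_a(X0) + grad.(p - X0)
        phi0 = np.zeros((self.n_cells, 4))
        phi0[:, 0] = 1.0
        return phi0 + np.einsum("mai,mi->ma", G, p - bary)

    def _inside(self, c: int, p: np.ndarray, tol: float) -> bool:
        G = self.grad_phi[c]
        X0 = self.cell_points[c, 0]
        lam = np.array([1.0, 0.0, 0.0, 0.0]) + G @ (p - X0)
        return bool(np.all(lam >= -tol))

    def interpolate(self, nodal: np.ndarray, pts: np.ndarray):
        """P1-interpolate a nodal field at arbitrary points.

        Returns (values, inside_mask); values are nan where a point falls
        outside the mesh.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        nodal = np.asarray(nodal, dtype=float)
        cells = self.find_cells(pts)
        inside = cells >= 0
        extra = nodal.shape[1:] if nodal.ndim > 1 else ()
        vals = np.full((pts.shape[0],) + extra, np.nan)
        for i in np.nonzero(inside)[0]:
            c = cells[i]
            G = self.grad_phi[c]
            X0 = self.cell_points[c, 0]
            lam = np.array([1.0, 0.0, 0.0, 0.0]) + G @ (pts[i] - X0)
            vals[i] = np.tensordot(lam, nodal[self.cells[c]], axes=(0, 0))
        return vals, inside
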