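"""Diffusion and preferential-direction tensor fields and their deformation.

The initial water diffusion tensor D0 (from DTI) is decomposed spectrally,
D0 = sum_i lambda_i e_i x e_i with descending eigenvalues.  The tensor of
preferential directions A0 shares its eigenvectors but has anisotropy
enhanced by a control parameter r >= 1 and is trace-normalized to 3.
Under a deformation F the fibre *directions* rotate with F e_i (normalized:
stretching a fibre does not change how fast substances diffuse along it);
eigenvalues are kept, so tr(D) is preserved.  Lagrangian pullbacks
J F^-1 T F^-T carry the spatial tensors back to the reference mesh.

Conventions: symmetric tensors stored as full (..., 3, 3) arrays; the
six-component voxel ordering is xx, xy, xz, yy, yz, zz.  Diffusivities in
mm^2/day, lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SYM6_ORDER = ("xx", "xy", "xz", "yy", "yz", "zz")
_IJ = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def sym6_to_mat(sym6: np.ndarray) -> np.ndarray:
    """(..., 6) components in xx,xy,xz,yy,yz,zz order -> (..., 3, 3) symmetric."""
    sym6 = np.asarray(sym6, dtype=float)
    out = np.empty(sym6.shape[:-1] + (3, 3), dtype=float)
    for k, (i, j) in enumerate(_IJ):
        out[..., i, j] = sym6[..., k]
        out[..., j, i] = sym6[..., k]
    return out


def mat_to_sym6(mat: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric -> (..., 6) components in xx,xy,xz,yy,yz,zz order."""
    mat = np.asarray(mat, dtype=float)
    return np.stack([mat[..., i, j] for i, j in _IJ], axis=-1)


def spectral(T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition with *descending* eigenvalues.

    Returns (lams, vecs) with lams (..., 3) sorted lambda1 >= lambda2 >= lambda3
    and vecs (..., 3, 3) whose columns vecs[..., :, i] are the corresponding
    orthonormal eigenvectors.  Ties are kept in the stable order returned by
    the symmetric eigensolver.
    """
    lams, vecs = np.linalg.eigh(np.asarray(T, dtype=float))
    return lams[..., ::-1], vecs[..., ::-1]


def _check_ordered(l1, l2, l3, positive=True):
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    if np.any(l1 < l2 - 1e-14) or np.any(l2 < l3 - 1e-14):
        raise ValueError("eigenvalues must be in descending order")
    if positive and np.any(l3 <= 0.0):
        raise ValueError("eigenvalues must be strictly positive")
    return l1, l2, l3


def anisotropy_indices(l1, l2, l3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear, planar and spherical anisotropy indices of a diffusion tensor.

    a_l = (l1-l2)/tr, a_p = 2(l2-l3)/tr, a_s = 3 l3/tr; each lies in [0, 1]
    and the three sum to one exactly.
    """
    l1, l2, l3 = _check_ordered(l1, l2, l3)
    tr = l1 + l2 + l3
    return (l1 - l2) / tr, 2.0 * (l2 - l3) / tr, 3.0 * l3 / tr


def anisotropy_weights(r: float, l1, l2, l3) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalue weights a1(r), a2(r) enhancing anisotropy without rotating it.

    a1 = r a_l + r a_p + a_s, a2 = a_l + r a_p + a_s; r = 1 gives (1, 1)
    (no enhancement) because the indices sum to one.
    """
    if r < 1.0:
        raise ValueError("anisotropy enhancement r must be >= 1")
    a_l, a_p, a_s = anisotropy_indices(l1, l2, l3)
    return r * a_l + r * a_p + a_s, a_l + r * a_p + a_s


def _recompose(lams: np.ndarray, vecs: np.ndarray, weights) -> np.ndarray:
    # sum_i w_i lam_i v_i x v_i with vecs columns as eigenvectors
    w = np.stack([np.broadcast_to(np.asarray(wi, dtype=float), lams[..., 0].shape)
                  for wi in weights], axis=-1)
    return np.einsum("...i,...ji,...ki->...jk", w * lams, vecs, vecs)


def build_preferential_tensor(D0: np.ndarray, r: float = 1.0) -> np.ndarray:
    """Tensor of preferential directions A0 from the diffusion tensor D0.

    Ahat0 = a1(r) l1 e1xe1 + a2(r) l2 e2xe2 + l3 e3xe3, then normalized by its
    mean eigenvalue so that tr(A0) = 3.  For r = 1 this reduces to
    3 D0 / tr(D0); an isotropic D0 maps to the identity for every r.
    """
    lams, vecs = spectral(D0)
    if np.any(lams[..., 2] <= 0.0):
        raise ValueError("D0 must be positive-definite")
    a1, a2 = anisotropy_weights(r, lams[..., 0], lams[..., 1], lams[..., 2])
    Ahat = _recompose(lams, vecs, (a1, a2, np.ones_like(a1)))
    Aav = np.trace(Ahat, axis1=-2, axis2=-1)[..., None, None] / 3.0
    return Ahat / Aav


def reorient_tensor(lams: np.ndarray, vecs: np.ndarray, F: np.ndarray,
                    weights=None, normalize_trace_to: float | None = None) -> np.ndarray:
    """Deform the eigenframe of a spectral tensor by F, keeping eigenvalues.

    Returns sum_i w_i lam_i (F e_i x F e_i)/|F e_i|^2 with w = (1,1,1) by
    default (diffusion tensor: trace preserved unconditionally).  With
    ``normalize_trace_to`` the result is rescaled to that trace (used for the
    preferential-direction tensor, trace 3).
    """
    F = np.asarray(F, dtype=float)
    if np.any(np.linalg.det(F) <= 0.0):
        raise ValueError("F must have positive determinant")
    lams = np.asarray(lams, dtype=float)
    vecs = np.asarray(vecs, dtype=float)
    if weights is None:
        weights = (np.ones(lams.shape[:-1]),) * 3
    Fe = F @ vecs  # columns are F e_i
    nrm2 = np.sum(Fe**2, axis=-2)
    w = np.stack([np.broadcast_to(np.asarray(wi, dtype=float), lams[..., 0].shape)
                  for wi in weights], axis=-1)
    T = np.einsum("...i,...ji,...ki->...jk", w * lams / nrm2, Fe, Fe)
    if normalize_trace_to is not None:
        tr = np.trace(T, axis1=-2, axis2=-1)[..., None, None]
        T = T * (normalize_trace_to / tr)
    return T


def pullback_tensor(T: np.ndarray, F: np.ndarray, J=None) -> np.ndarray:
    """Lagrangian pullback J F^-1 T F^-T of a spatial second-order tensor."""
    F = np.asarray(F, dtype=float)
    det = np.linalg.det(F)
    if np.any(det <= 0.0):
        raise ValueError("F must have positive determinant")
    if J is None:
        J = det
    Finv = np.linalg.inv(F)
    return np.asarray(J, dtype=float)[..., None, None] * (
        Finv @ np.asarray(T, dtype=float) @ np.swapaxes(Finv, -1, -2))


def fractional_anisotropy(l1, l2, l3) -> np.ndarray:
    """Fractional anisotropy in [0, 1]: 0 for isotropic, -> 1 for a single direction.

    FA = sqrt(1/2 ((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2) / (l1^2+l2^2+l3^2)).
    """
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    denom = l1**2 + l2**2 + l3**2
    if np.any(denom <= 0.0):
        raise ValueError("eigenvalues must not all be zero")
    if np.any(np.minimum(np.minimum(l1, l2), l3) < -1e-14):
        raise ValueError("eigenvalues must be non-negative")
    num = 0.5 * ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2)
    return np.sqrt(num / denom)


def _wrap_axis_angle(d):
    """Fold angle differences of an *axis* (not an orientation) into [0, pi/2]."""
    d = np.mod(np.abs(d), np.pi)
    return np.where(d > np.pi / 2.0, np.pi - d, d)


def _canonical_axis(e: np.ndarray) -> np.ndarray:
    """Flip each unit vector into the canonical hemisphere (z > 0, ties by y, x)."""
    sign = np.sign(e[..., 2])
    tie = sign == 0.0
    if np.any(tie):
        sign = np.where(tie, np.sign(e[..., 1]), sign)
        sign = np.where(sign == 0.0, np.sign(e[..., 0]), sign)
    return e * sign[..., None]


def eigenvector_change(e0: np.ndarray, ef: np.ndarray):
    """Change of the principal diffusion axis between two unit vectors.

    Returns (s, |dtheta|, |dphi|): s = 1 - |e0 . ef| (0 for the same axis,
    also for opposite orientation; 1 for perpendicular axes), and the absolute
    variations of the azimuthal and polar spherical angles.  Because only the
    axis matters, both vectors are first mapped to a canonical hemisphere;
    azimuths differing by multiples of pi are identified, and both angle
    variations land in [0, pi/2].
    """
    e0 = np.asarray(e0, dtype=float)
    ef = np.asarray(ef, dtype=float)
    n0 = np.linalg.norm(e0, axis=-1)
    nf = np.linalg.norm(ef, axis=-1)
    if np.any(n0 == 0.0) or np.any(nf == 0.0):
        raise ValueError("eigenvectors must be non-zero")
    e0 = _canonical_axis(e0 / n0[..., None])
    ef = _canonical_axis(ef / nf[..., None])
    s = 1.0 - np.abs(np.sum(e0 * ef, axis=-1))
    s = np.clip(s, 0.0, 1.0)
    theta0 = np.arctan2(e0[..., 1], e0[..., 0])
    thetaf = np.arctan2(ef[..., 1], ef[..., 0])
    phi0 = np.arccos(np.clip(e0[..., 2], -1.0, 1.0))
    phif = np.arccos(np.clip(ef[..., 2], -1.0, 1.0))
    return s, _wrap_axis_angle(thetaf - theta0), np.abs(phif - phi0)


@dataclass
class VoxelTensorGrid:
    """Regular voxel grid of symmetric tensors (components xx,xy,xz,yy,yz,zz).

    ``data`` has shape (nx, ny, nz, 6); ``origin`` is the coordinate of the
    corner of voxel (0,0,0) and ``spacing`` the voxel edge lengths [mm].
    Voxel i owns the half-open interval [origin + i*spacing,
    origin + (i+1)*spacing) along each axis.
    """

    data: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError("voxel data must have shape (nx, ny, nz, 6)")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0.0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel indices of the voxels owning the given points."""
        idx = np.floor((np.asarray(points, dtype=float) - self.origin)
                       / self.spacing).astype(int)
        return idx

    def save_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data, affine), str(path))

    @classmethod
    def load_nifti(cls, path) -> "VoxelTensorGrid":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
            raise ValueError("only axis-aligned voxel grids are supported")
        return cls(data=np.asarray(img.dataobj, dtype=float),
                   origin=affine[:3, 3], spacing=np.diag(affine[:3, :3]))


def voxel_to_cell(grid: VoxelTensorGrid, mesh) -> np.ndarray:
    """Sample a voxel tensor grid onto mesh cells by barycentre ownership.

    Each cell receives the tensor of the voxel containing its barycentre
    (half-open voxel intervals).  Raises, naming the first offending cell, if
    a barycentre falls outside the grid.

    Returns a (n_cells, 3, 3) array.
    """
    bary = mesh.barycenters
    idx = grid.voxel_of(bary)
    shape = np.array(grid.shape)
    bad = np.any((idx < 0) | (idx >= shape), axis=1)
    if np.any(bad):
        cell = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"cell {cell} barycentre {bary[cell]} lies outside the voxel grid")
    return sym6_to_mat(grid.data[idx[:, 0], idx[:, 1], idx[:, 2]])
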