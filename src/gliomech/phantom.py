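"""Synthetic inputs standing in for patient MRI/DTI data.

A "brain phantom" is a ball-shaped domain bounded by a rigid outer surface
(the skull), carrying a smooth spherical tumour indicator and a voxel grid
of diffusion tensors with controllable anisotropy.  The generator writes
the same in-memory objects (and on-disk formats) the solver consumes, so a
full phantom -> simulate -> postprocess pipeline needs no clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .mesh import TetMesh
from .tensors import VoxelTensorGrid, mat_to_sym6

DTI_MODES = ("isotropic", "uniform_axis", "radial")


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the synthetic brain phantom.

    brain_radius     outer (skull) radius [mm]
    h                background mesh size [mm]
    refine_factor    mesh-size reduction inside the refinement ball around the
                     tumour centre (1 = uniform mesh)
    tumour_centre    tumour centre in the reference frame [mm]
    tumour_radius    radius of the chi = 1/2 level of the indicator [mm]
    interface_width  tanh half-width of the diffuse interface [mm]
    dti_mode         isotropic | uniform_axis | radial
    eigenvalues      descending diffusion eigenvalues [mm^2/day]
    axis             principal direction for uniform_axis mode
    voxel_spacing    DTI voxel edge length [mm]
    seed             reproducibility seed (jitter of interior lattice points)
    """

    brain_radius: float = 40.0
    h: float = 8.0
    refine_factor: float = 1.0
    tumour_centre: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tumour_radius: float = 7.0
    interface_width: float = 1.0
    dti_mode: str = "isotropic"
    eigenvalues: tuple[float, float, float] = (86.4, 86.4, 86.4)
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    voxel_spacing: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dti_mode not in DTI_MODES:
            raise ValueError(f"dti_mode must be one of {DTI_MODES}")
        lam = self.eigenvalues
        if not (lam[0] >= lam[1] >= lam[2] > 0.0):
            raise ValueError("eigenvalues must be positive and descending")
        margin = self.h
        centre = np.linalg.norm(self.tumour_centre)
        if centre + self.tumour_radius + self.interface_width > self.brain_radius - margin:
            raise ValueError("tumour (incl. interface) must fit inside the brain "
                             "with at least one mesh size of margin")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1)


def _bcc_lattice(radius: float, h: float) -> np.ndarray:
    """Body-centred-cubic points covering a ball (good Delaunay tet quality)."""
    n = int(np.ceil(radius / h)) + 1
    ax = np.arange(-n, n + 1) * h
    cubic = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    centred = cubic + 0.5 * h
    return np.concatenate([cubic, centred])


def make_ball_mesh(spec: PhantomSpec) -> TetMesh:
    """Conforming tetrahedral mesh of the brain ball.

    Interior nodes come from a BCC lattice (optionally refined inside a ball
    around the tumour centre), boundary nodes from a Fibonacci covering of
    the sphere; the tetrahedra are their Delaunay triangulation.  The chordal
    gap makes the mesh volume approach 4/3 pi R^3 from below as h -> 0.
    """
    R, h = spec.brain_radius, spec.h
    if h <= 0.0:
        raise ValueError("mesh size h must be positive")
    rng = np.random.default_rng(spec.seed)
    centre = np.asarray(spec.tumour_centre, dtype=float)
    r_refine = spec.tumour_radius + spec.interface_width + 0.3 * h

    pts = _bcc_lattice(R, h)
    # keep interior points clear of the boundary shell
    keep = np.linalg.norm(pts, axis=1) <= R - 0.55 * h
    pts = pts[keep]
    if spec.refine_factor > 1.0:
        hf = h / spec.refine_factor
        fine = _bcc_lattice(r_refine + h, hf) + centre
        fine_keep = (np.linalg.norm(fine - centre, axis=1) <= r_refine) & (
            np.linalg.norm(fine, axis=1) <= R - 0.55 * h)
        fine = fine[fine_keep]
        # carve out coarse points inside / hugging the refined region
        coarse_keep = np.linalg.norm(pts - centre, axis=1) > r_refine + 0.45 * h
        pts = np.concatenate([pts[coarse_keep], fine])
    # tiny deterministic jitter removes the degenerate cospherical point sets
    # a perfect lattice feeds to Delaunay
    pts = pts + rng.uniform(-0.05, 0.05, size=pts.shape) * min(
        h, h / max(spec.refine_factor, 1.0))

    n_surf = max(64, int(np.ceil(4.0 * np.pi * R**2 / (0.6 * h**2))))
    surf = R * _fibonacci_sphere(n_surf)
    points = np.concatenate([pts, surf])

    tri = Delaunay(points)
    mesh = TetMesh(points=points, cells=tri.simplices).orient()
    mesh = _drop_unused_points(mesh)
    mesh.validate()
    return mesh


def _drop_unused_points(mesh: TetMesh) -> TetMesh:
    used = np.unique(mesh.cells)
    remap = -np.ones(mesh.n_points, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return TetMesh(points=mesh.points[used], cells=remap[mesh.cells])


def make_indicator(mesh: TetMesh, centre, r0: float, w: float) -> np.ndarray:
    """Smooth tumour indicator chi(X) = (1 - tanh((|X - centre| - r0)/w))/2.

    chi = 1/2 on the sphere |X - centre| = r0; the conventional chi > 0.1
    tumour region is the ball of radius r0 + w atanh(0.8).
    """
    if w <= 0.0:
        raise ValueError("interface width w must be positive")
    d = np.linalg.norm(mesh.points - np.asarray(centre, dtype=float), axis=1)
    return 0.5 * (1.0 - np.tanh((d - r0) / w))


def indicator_level_radius(r0: float, w: float, level: float = 0.1) -> float:
    """Radius of the {chi > level} ball of the tanh indicator."""
    return r0 + w * np.arctanh(1.0 - 2.0 * level)


def make_synthetic_dti(spec: PhantomSpec) -> VoxelTensorGrid:
    """Voxel grid of symmetric positive-definite diffusion tensors.

    isotropic     lambda_mean I in every voxel (FA = 0)
    uniform_axis  fixed eigenframe everywhere, principal axis ``spec.axis``
    radial        principal axis along the radial direction from the domain
                  centre (an arbitrary fixed axis at the centre voxel)
    """
    R = spec.brain_radius
    s = float(spec.voxel_spacing)
    n = int(np.ceil(2.0 * (R + 2.0 * s) / s))
    origin = -0.5 * n * s * np.ones(3)
    ax = origin[0] + (np.arange(n) + 0.5) * s
    Xc, Yc, Zc = np.meshgrid(ax, ax, ax, indexing="ij")
    centres = np.stack([Xc, Yc, Zc], axis=-1)
    lam = np.asarray(spec.eigenvalues, dtype=float)

    if spec.dti_mode == "isotropic":
        T = np.zeros(centres.shape[:3] + (3, 3))
        T[..., 0, 0] = T[..., 1, 1] = T[..., 2, 2] = lam.mean()
    elif spec.dti_mode == "uniform_axis":
        e1 = np.asarray(spec.axis, dtype=float)
        e1 = e1 / np.linalg.norm(e1)
        helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        T0 = lam[0] * np.outer(e1, e1) + lam[1] * np.outer(e2, e2) + lam[2] * np.outer(e3, e3)
        T = np.broadcast_to(T0, centres.shape[:3] + (3, 3)).copy()
    else:  # radial
        r = np.linalg.norm(centres, axis=-1)
        e1 = np.where(r[..., None] > 1e-12, centres / np.maximum(r, 1e-12)[..., None],
                      np.array([1.0, 0.0, 0.0]))
        helper = np.broadcast_to(np.array([0.0, 0.0, 1.0]), e1.shape).copy()
        swap = np.abs(e1[..., 2]) >= 0.9
        helper[swap] = np.array([1.0, 0.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
        e3 = np.cross(e1, e2)
        T = (lam[0] * e1[..., :, None] * e1[..., None, :]
             + lam[1] * e2[..., :, None] * e2[..., None, :]
             + lam[2] * e3[..., :, None] * e3[..., None, :])

    return VoxelTensorGrid(data=mat_to_sym6(T), origin=origin,
                           spacing=np.full(3, s))
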