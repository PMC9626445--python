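"""Derived quantities: volume growth metrics, ray profiles, anisotropy changes.

Volume metrics follow radiological conventions: the volume doubling time
(VDT) is the first time the tumour volume reaches twice its initial value;
the specific growth rate SGR = 100 ln2 / VDT [%/day]; the velocity of
radial expansion (VRE) is the mean slope of the equivalent-sphere radius
r(t) = (3V/(4 pi))^(1/3), reported in mm/year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh
from .tensors import eigenvector_change, fractional_anisotropy, spectral

DAYS_PER_YEAR = 365.0
FA_MASK_THRESHOLD = 0.1  # eigenvector-change metrics only where FA exceeds this


@dataclass(frozen=True)
class GrowthMetrics:
    vdt: float          # day; nan if the volume never doubles
    sgr: float          # %/day; nan with vdt
    vre: float          # mm/year
    doubled: bool


def tumour_volume(mesh: TetMesh, chi: np.ndarray, J_cell: np.ndarray,
                  threshold: float = 0.1) -> float:
    """Deformed volume [cm^3] of the reference cells with chi(barycentre) > threshold."""
    chi_cell = mesh.cell_mean(np.asarray(chi, dtype=float))
    mask = chi_cell > threshold
    return float(np.sum(np.asarray(J_cell, dtype=float)[mask]
                        * mesh.volumes[mask]) / 1e3)


def growth_metrics(times: np.ndarray, volumes: np.ndarray) -> GrowthMetrics:
    """VDT (linear interpolation between outputs), SGR and mean VRE."""
    t = np.asarray(times, dtype=float)
    V = np.asarray(volumes, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two time points")
    if np.any(V <= 0.0):
        raise ValueError("volumes must be positive")
    target = 2.0 * V[0]
    vdt = np.nan
    doubled = False
    above = np.nonzero(V >= target)[0]
    if above.size:
        i = int(above[0])
        doubled = True
        if i == 0:
            vdt = 0.0
        else:
            f = (target - V[i - 1]) / (V[i] - V[i - 1])
            vdt = t[i - 1] + f * (t[i] - t[i - 1])
    sgr = 100.0 * np.log(2.0) / vdt if doubled and vdt > 0 else np.nan
    radii = (3.0 * V * 1e3 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    vre = (radii[-1] - radii[0]) / (t[-1] - t[0]) * DAYS_PER_YEAR
    return GrowthMetrics(vdt=float(vdt), sgr=float(sgr), vre=float(vre),
                         doubled=doubled)


def ray_profile(mesh: TetMesh, nodal_field: np.ndarray, origin, direction,
                length: float, n_samples: int = 50):
    """P1-interpolated samples of a nodal field along a ray (reference frame).

    Returns (arc_lengths, values); samples outside the mesh are dropped (the
    profile is truncated) and a warning flag is the third return value.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    s = np.linspace(0.0, length, n_samples)
    pts = np.asarray(origin, dtype=float) + s[:, None] * direction
    vals, inside = mesh.interpolate(np.asarray(nodal_field, dtype=float), pts)
    truncated = not bool(np.all(inside))
    return s[inside], vals[inside], truncated


def ray_profile_cells(mesh: TetMesh, cell_values: np.ndarray, origin, direction,
                      length: float, n_samples: int = 50):
    """Piecewise-constant samples of a cell field along a ray.

    Used for cellwise quantities such as Sigma or a Cauchy stress component
    (e.g. T_zz along a tumour diameter).  Returns (arc_lengths, values,
    truncated) like :func:`ray_profile`.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    s = np.linspace(0.0, length, n_samples)
    pts = np.asarray(origin, dtype=float) + s[:, None] * direction
    cells = mesh.find_cells(pts)
    inside = cells >= 0
    vals = np.asarray(cell_values, dtype=float)[cells[inside]]
    return s[inside], vals, not bool(np.all(inside))


def cell_field_fa(D_cells: np.ndarray) -> np.ndarray:
    """Fractional anisotropy per cell of a (M, 3, 3) tensor field."""
    lams, _ = spectral(D_cells)
    return fractional_anisotropy(lams[:, 0], lams[:, 1], lams[:, 2])


@dataclass(frozen=True)
class AnisotropyChange:
    """Cellwise anisotropy-change maps between an initial and final tensor field.

    dFA is defined everywhere; the principal-axis change metrics (s, |dtheta|,
    |dphi|) are nan outside the FA mask (cells whose initial diffusion is too
    close to spherical for a principal axis to be meaningful).
    """

    dFA: np.ndarray
    s: np.ndarray
    dtheta: np.ndarray
    dphi: np.ndarray
    mask: np.ndarray


def anisotropy_change_maps(D0_cells: np.ndarray, Df_cells: np.ndarray,
                           fa_threshold: float = FA_MASK_THRESHOLD) -> AnisotropyChange:
    """Per-cell Delta FA and principal-eigenvector change between two tensor fields."""
    D0_cells = np.asarray(D0_cells, dtype=float)
    Df_cells = np.asarray(Df_cells, dtype=float)
    if D0_cells.shape != Df_cells.shape:
        raise ValueError("initial and final tensor fields must have matching cells")
    lam0, vec0 = spectral(D0_cells)
    lamf, vecf = spectral(Df_cells)
    fa0 = fractional_anisotropy(lam0[:, 0], lam0[:, 1], lam0[:, 2])
    faf = fractional_anisotropy(lamf[:, 0], lamf[:, 1], lamf[:, 2])
    dFA = faf - fa0
    mask = fa0 > fa_threshold
    s = np.full(fa0.shape, np.nan)
    dth = np.full(fa0.shape, np.nan)
    dph = np.full(fa0.shape, np.nan)
    if np.any(mask):
        sm, tm, pm = eigenvector_change(vec0[mask][:, :, 0], vecf[mask][:, :, 0])
        s[mask], dth[mask], dph[mask] = sm, tm, pm
    return AnisotropyChange(dFA=dFA, s=s, dtheta=dth, dphi=dph, mask=mask)
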