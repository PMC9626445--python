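"""Pointwise finite-strain kinematics and the hyperelastic constitutive law.

The solid phase deformation gradient is split multiplicatively into an
isotropic growth distortion F_g = g I and an elastic accommodation F_e,
F_s = F_e F_g.  The elastic response is an isochoric two-parameter
Mooney-Rivlin energy plus a logarithmic volumetric term,

    W(C_e) = mu1/2 (I_Cbar - 3) + mu2/2 (II_Cbar - 3) + kappa/2 (ln J_e)^2,

with Cbar_e = J_e^(-2/3) C_e.  All functions are vectorized: tensor
arguments may carry arbitrary leading batch axes, i.e. shape (..., 3, 3).

Units: stresses in MPa, lengths in mm, times in day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MaterialParams, PermeabilityParams

_I3 = np.eye(3)


@dataclass(frozen=True)
class Kinematics:
    """Multiplicative-decomposition kinematics at a material point (batched)."""

    F_s: np.ndarray
    g: np.ndarray
    F_e: np.ndarray
    J_s: np.ndarray
    J_g: np.ndarray
    J_e: np.ndarray
    C_e: np.ndarray
    Cbar_e: np.ndarray


@dataclass(frozen=True)
class StressState:
    """Solid-phase Cauchy stress and derived measures (batched).

    T_s     constitutive Cauchy stress of the solid phase [MPa]
    T_s_dev traceless (deviatoric) part
    T_s_vol spherical part, kappa ln(J_e)/J_e I
    P_s     constitutive first Piola-Kirchhoff stress, J_s T_s F_s^-T
    Sigma   compression measure -tr(T_s)/3 [MPa], positive in compression
    """

    T_s: np.ndarray
    T_s_dev: np.ndarray
    T_s_vol: np.ndarray
    P_s: np.ndarray
    Sigma: np.ndarray


class InvertedElementError(RuntimeError):
    """Raised when det(F_s) <= 0, i.e. the deformation locally inverts."""


class CompactionError(RuntimeError):
    """Raised when J_e falls to the pore-closure limit phi_sn."""


def compute_kinematics(grad_u: np.ndarray, g) -> Kinematics:
    """Kinematic quantities from the material displacement gradient and growth field.

    Parameters
    ----------
    grad_u : (..., 3, 3) array
        Material gradient of the solid displacement, Grad u_s.
    g : scalar or (...) array
        Isotropic growth stretch, g >= 1 (F_g = g I).
    """
    grad_u = np.asarray(grad_u, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(g < 1.0 - 1e-12):
        raise ValueError("growth stretch g must be >= 1")
    F_s = grad_u + _I3
    J_s = np.linalg.det(F_s)
    if np.any(J_s <= 0.0):
        raise InvertedElementError("det(F_s) <= 0: inverted material element")
    F_e = F_s / g[..., None, None]
    J_g = g**3
    J_e = J_s / J_g
    C_e = np.swapaxes(F_e, -1, -2) @ F_e
    Cbar_e = J_e[..., None, None] ** (-2.0 / 3.0) * C_e
    return Kinematics(F_s=F_s, g=g, F_e=F_e, J_s=J_s, J_g=J_g, J_e=J_e, C_e=C_e, Cbar_e=Cbar_e)


def _invariants(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1**2 - np.trace(C @ C, axis1=-2, axis2=-1))
    return I1, I2


def isochoric_energy(Cbar_e: np.ndarray, mu1: float, mu2: float) -> np.ndarray:
    """Mooney-Rivlin isochoric strain energy density [MPa], zero at Cbar_e = I."""
    Cbar_e = np.asarray(Cbar_e, dtype=float)
    if not np.allclose(Cbar_e, np.swapaxes(Cbar_e, -1, -2), atol=1e-10):
        raise ValueError("Cbar_e must be symmetric")
    I1, I2 = _invariants(Cbar_e)
    return 0.5 * mu1 * (I1 - 3.0) + 0.5 * mu2 * (I2 - 3.0)


def volumetric_energy(J_e, kappa: float) -> np.ndarray:
    """Logarithmic volumetric strain energy density kappa/2 (ln J_e)^2 [MPa]."""
    J_e = np.asarray(J_e, dtype=float)
    if np.any(J_e <= 0.0):
        raise ValueError("J_e must be positive")
    return 0.5 * kappa * np.log(J_e) ** 2


def total_energy(kin: Kinematics, mu1: float, mu2: float, kappa: float) -> np.ndarray:
    """Strain energy density per unit natural-state volume [MPa]."""
    return isochoric_energy(kin.Cbar_e, mu1, mu2) + volumetric_energy(kin.J_e, kappa)


def _cauchy_one_material(kin: Kinematics, mu1: float, mu2: float, kappa: float):
    """Closed-form Cauchy stress for one parameter set; returns (T_dev, T_vol)."""
    J_e = kin.J_e[..., None, None]
    Bbar = J_e ** (-2.0 / 3.0) * (kin.F_e @ np.swapaxes(kin.F_e, -1, -2))
    I1 = np.trace(Bbar, axis1=-2, axis2=-1)[..., None, None]
    M = mu1 * Bbar + mu2 * (I1 * Bbar - Bbar @ Bbar)
    T_dev = (M - np.trace(M, axis1=-2, axis2=-1)[..., None, None] / 3.0 * _I3) / J_e
    T_vol = kappa * np.log(kin.J_e)[..., None, None] / J_e * _I3
    return T_dev, T_vol


def cauchy_stress(kin: Kinematics, params: MaterialParams, chi) -> StressState:
    """Blended solid-phase stress: T_s = chi T_s^t + (1 - chi) T_s^h.

    chi is the smooth tumour indicator in [0, 1], evaluated at the same
    points as the kinematics.  The deviatoric/spherical split is preserved
    by the blend.
    """
    chi = np.asarray(chi, dtype=float)[..., None, None]
    Td_t, Tv_t = _cauchy_one_material(kin, *params.tumour())
    Td_h, Tv_h = _cauchy_one_material(kin, *params.healthy())
    T_dev = chi * Td_t + (1.0 - chi) * Td_h
    T_vol = chi * Tv_t + (1.0 - chi) * Tv_h
    T_s = T_dev + T_vol
    FinvT = np.swapaxes(np.linalg.inv(kin.F_s), -1, -2)
    P_s = kin.J_s[..., None, None] * T_s @ FinvT
    return StressState(T_s=T_s, T_s_dev=T_dev, T_s_vol=T_vol, P_s=P_s,
                       Sigma=compression_measure(T_s))


def compression_measure(T_s: np.ndarray) -> np.ndarray:
    """Sigma = -tr(T_s)/3 [MPa]; positive when the tissue is in compression."""
    return -np.trace(T_s, axis1=-2, axis2=-1) / 3.0


def total_first_piola(kin: Kinematics, params: MaterialParams, chi, p) -> np.ndarray:
    """Total first Piola-Kirchhoff stress P = -J_s p F_s^-T + P_s [MPa]."""
    stress = cauchy_stress(kin, params, chi)
    FinvT = np.swapaxes(np.linalg.inv(kin.F_s), -1, -2)
    p = np.asarray(p, dtype=float)[..., None, None]
    return -kin.J_s[..., None, None] * p * FinvT + stress.P_s


def holmes_mow_k(J_e, params: PermeabilityParams) -> np.ndarray:
    """Holmes-Mow scalar hydraulic mobility k(J_e) [mm^2 MPa^-1 day^-1].

    k = k0 ((J_e - phi_sn)/(1 - phi_sn))^alpha0 exp(m (J_e^2 - 1)/2).
    Equals k0 in the natural state (J_e = 1) and vanishes as the pores close
    (J_e -> phi_sn).
    """
    J_e = np.asarray(J_e, dtype=float)
    if np.any(J_e <= params.phi_sn):
        raise CompactionError("J_e reached the pore-closure limit phi_sn: permeability undefined")
    x = (J_e - params.phi_sn) / (1.0 - params.phi_sn)
    return params.k0 * x**params.alpha0 * np.exp(params.m * (J_e**2 - 1.0) / 2.0)
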