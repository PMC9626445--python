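"""Growth-rate laws and pointwise updates of the growth stretch and solid fraction.

The tumour proliferates at a net volumetric rate

    Gamma_s = gamma phi_s (phi_max - phi_s) (c_n - c0)_+ ,

optionally reduced by compressive solid stress through the factor
1 - delta1 Sigma_+ / (Sigma_+ + delta2).  The growth stretch g obeys
g_dot / g = Gamma_s / (3 phi_s) inside the reference tumour region, and the
solid fraction follows from mass conservation J_s phi_s = g^3 phi_sn.
All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .params import GrowthParams


def positive_part(x, smooth_width: float = 0.0):
    """(x)_+ as a hard max by default; softplus of the given width if > 0.

    The smooth variant can be used where the positive part enters an implicit
    system and a differentiable kink helps Newton's method.
    """
    x = np.asarray(x, dtype=float)
    if smooth_width > 0.0:
        return smooth_width * np.logaddexp(0.0, x / smooth_width)
    return np.maximum(x, 0.0)


def stress_inhibition_factor(Sigma, delta1: float, delta2: float):
    """Growth reduction under compression: 1 - delta1 Sigma_+/(Sigma_+ + delta2).

    Traction (Sigma <= 0) does not inhibit; the factor decreases monotonically
    towards 1 - delta1 as the compression Sigma [MPa] grows.
    """
    if not delta1 < 1.0:
        raise ValueError("delta1 must be < 1")
    if not delta2 > 0.0:
        raise ValueError("delta2 must be > 0")
    Sp = positive_part(Sigma)
    return 1.0 - delta1 * Sp / (Sp + delta2)


def growth_rate(phi_s, c_n, params: GrowthParams, Sigma=None,
                smooth_width: float = 0.0):
    """Net volumetric proliferation rate Gamma_s [1/day].

    With Sigma given, applies the compressive stress-inhibition factor
    (Sigma in MPa, from the previous converged stress state).
    """
    phi_s = np.asarray(phi_s, dtype=float)
    c_n = np.asarray(c_n, dtype=float)
    rate = params.gamma * phi_s * (params.phi_max - phi_s) * positive_part(
        c_n - params.c0, smooth_width)
    if Sigma is not None:
        rate = rate * stress_inhibition_factor(Sigma, params.delta1, params.delta2)
    return rate


def nutrient_source(phi_s, phi_l, c_n, params: GrowthParams):
    """Nutrient source G_n = -zeta phi_s phi_l c_n + S_n (1 - c_n) phi_l [1/day]."""
    phi_s = np.asarray(phi_s, dtype=float)
    phi_l = np.asarray(phi_l, dtype=float)
    if not np.allclose(phi_s + phi_l, 1.0, atol=1e-12):
        raise ValueError("saturation violated: phi_s + phi_l must equal 1")
    c_n = np.asarray(c_n, dtype=float)
    return -params.zeta * phi_s * phi_l * c_n + params.S_n * (1.0 - c_n) * phi_l


def update_g(g_k, Gamma_s_k, phi_s_k, chi_ref, dt: float):
    """Explicit Euler update g_{k+1} = g_k (1 + dt Gamma_s/(3 phi_s) chi).

    chi_ref is the (fixed-in-time) reference tumour indicator; g never changes
    where chi_ref = 0 and never decreases for Gamma_s >= 0.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    g_k = np.asarray(g_k, dtype=float)
    phi_s_k = np.asarray(phi_s_k, dtype=float)
    if np.any(phi_s_k <= 0.0):
        raise ValueError("phi_s must be positive (corrupted state)")
    return g_k * (1.0 + dt * np.asarray(Gamma_s_k, dtype=float)
                  / (3.0 * phi_s_k) * np.asarray(chi_ref, dtype=float))


def update_phi_s(J_s, g, phi_sn: float):
    """Solid fraction from mass conservation: phi_s = (g^3 / J_s) phi_sn.

    Raises if the result leaves (0, 1): an elastic compression beyond the
    physical packing bound signals a corrupted or unresolvable state.
    """
    J_s = np.asarray(J_s, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(J_s <= 0.0):
        raise ValueError("J_s must be positive")
    phi_s = g**3 / J_s * phi_sn
    if np.any(phi_s >= 1.0) or np.any(phi_s <= 0.0):
        raise ValueError("saturation violation: phi_s left (0, 1)")
    return phi_s
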