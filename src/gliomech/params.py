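"""Model parameter containers.

Units are fixed globally across the package: lengths in mm, times in day,
stresses in MPa.  Defaults are the literature-based values for glioma growth
in human brain tissue (tumour roughly ten times stiffer than host).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MaterialParams:
    """Mooney-Rivlin and volumetric moduli for tumour ('t') and healthy ('h') tissue [MPa]."""

    mu1_t: float = 1.53e-3
    mu2_t: float = 2.97e-3
    kappa_t: float = 1.40e-3
    mu1_h: float = 1.53e-4
    mu2_h: float = 2.97e-4
    kappa_h: float = 1.40e-4

    def __post_init__(self) -> None:
        for name in ("mu1_t", "mu2_t", "kappa_t", "mu1_h", "mu2_h", "kappa_h"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"material parameter {name} must be strictly positive")

    def tumour(self) -> tuple[float, float, float]:
        return self.mu1_t, self.mu2_t, self.kappa_t

    def healthy(self) -> tuple[float, float, float]:
        return self.mu1_h, self.mu2_h, self.kappa_h


@dataclass(frozen=True)
class PermeabilityParams:
    """Holmes-Mow permeability law parameters.

    k0 is the reference hydraulic mobility in the natural state
    [mm^2 MPa^-1 day^-1]; alpha0 and m shape the dependence on the elastic
    volume change J_e; phi_sn is the solid fraction in the natural state
    (the pore space closes as J_e -> phi_sn).
    """

    k0: float = 2.17e5
    alpha0: float = 0.0848
    m: float = 4.638
    phi_sn: float = 0.3

    def __post_init__(self) -> None:
        if self.k0 <= 0.0:
            raise ValueError("k0 must be positive")
        if self.alpha0 <= 0.0:
            raise ValueError("alpha0 must be positive")
        if not 0.0 < self.phi_sn < 1.0:
            raise ValueError("phi_sn must lie in (0, 1)")


@dataclass(frozen=True)
class GrowthParams:
    """Proliferation, nutrient and stress-inhibition parameters.

    gamma   cell proliferation constant [1/day]
    c0      hypoxia threshold (normalized nutrient concentration)
    phi_max maximum cell packing fraction (contact inhibition)
    delta1  maximum relative growth reduction under compression (< 1)
    delta2  compression scale of the inhibition response [MPa]
    zeta    nutrient consumption rate by tumour cells [1/day]
    S_n     nutrient supply rate from the vasculature [1/day]
    phi_sn  solid fraction in the natural state
    """

    gamma: float = 0.5
    c0: float = 0.3
    phi_max: float = 0.85
    delta1: float = 0.8
    delta2: float = 1.0e-4
    zeta: float = 8640.0
    S_n: float = 1.0e4
    phi_sn: float = 0.3

    def __post_init__(self) -> None:
        if self.gamma < 0.0:
            raise ValueError("gamma must be non-negative")
        if not 0.0 < self.c0 < 1.0:
            raise ValueError("c0 must lie in (0, 1)")
        if not self.phi_sn < self.phi_max < 1.0:
            raise ValueError("need phi_sn < phi_max < 1")
        if not 0.0 <= self.delta1 < 1.0:
            raise ValueError("delta1 must lie in [0, 1)")
        if self.delta2 <= 0.0:
            raise ValueError("delta2 must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all constitutive parameter blocks."""

    material: MaterialParams = field(default_factory=MaterialParams)
    permeability: PermeabilityParams = field(default_factory=PermeabilityParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
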