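"""Viscoelastic material description for the cell model.

Cytoplasm and nucleus are isotropic, homogeneous standard-linear-solid
(one-term Prony) materials: the shear modulus relaxes as

    G(t) = G_inf + (G0 - G_inf) * exp(-t / tau)

between the instantaneous modulus G0 and the long-term modulus G_inf,
while the bulk response is elastic with K derived from (G0, nu).
Default constants (kPa, s): nucleus G0=3.8, G_inf=2.0, nu=0.3, tau=0.3;
cytoplasm G0=1.8, G_inf=0.9, nu=0.37, tau=0.3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PronyMaterial:
    """One-term Prony (standard linear solid) shear relaxation material.

    Parameters
    ----------
    G0, G_inf : float
        Instantaneous and long-term shear moduli in kPa; G0 >= G_inf > 0.
    poisson_ratio : float
        Poisson's ratio (instantaneous), in (0, 0.5).
    tau : float
        Relaxation time constant in seconds.
    """

    G0: float
    G_inf: float
    poisson_ratio: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.G0 >= self.G_inf > 0):
            raise ValueError("require G0 >= G_inf > 0")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def G0_pa(self) -> float:
        return self.G0 * 1e3

    @property
    def G_inf_pa(self) -> float:
        return self.G_inf * 1e3

    @property
    def bulk_modulus_pa(self) -> float:
        """Elastic bulk modulus from (G0, nu): K = 2 G0 (1+nu) / (3 (1-2nu))."""
        nu = self.poisson_ratio
        return 2.0 * self.G0_pa * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))

    @property
    def E0_pa(self) -> float:
        """Instantaneous Young's modulus E0 = 2 G0 (1 + nu)."""
        return 2.0 * self.G0_pa * (1.0 + self.poisson_ratio)

    @property
    def E_inf_pa(self) -> float:
        """Long-term Young's modulus consistent with elastic bulk K.

        With only the shear modulus relaxing, the long-term uniaxial modulus
        is 9 K G_inf / (3 K + G_inf), not 2 G_inf (1 + nu).
        """
        K, G = self.bulk_modulus_pa, self.G_inf_pa
        return 9.0 * K * G / (3.0 * K + G)

    def shear_relaxation(self, t) -> np.ndarray:
        """G(t) in Pa for t >= 0."""
        t = np.asarray(t, dtype=float)
        return self.G_inf_pa + (self.G0_pa - self.G_inf_pa) * np.exp(-t / self.tau)


#: Table defaults for the two cell regions (kPa, -, s).
NUCLEUS = PronyMaterial(G0=3.8, G_inf=2.0, poisson_ratio=0.3, tau=0.3)
CYTOPLASM = PronyMaterial(G0=1.8, G_inf=0.9, poisson_ratio=0.37, tau=0.3)

DEFAULT_MATERIALS = {"cytoplasm": CYTOPLASM, "nucleus": NUCLEUS}
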