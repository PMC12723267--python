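"""Physical constants and elementary optical relations.

Units throughout the package: lengths in mm, time in ns, absorption and
reduced scattering coefficients in mm^-1, modulation frequency supplied in
MHz and converted internally to an angular frequency in rad/ns.  With these
choices the entries of the FEM system matrix stay O(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: speed of light in vacuum, mm/ns
C_VACUUM = 299.792458


def _effective_reflection(n: float) -> float:
    # Groenhuis polynomial fit for the internal reflection coefficient of a
    # refractive-index-mismatched tissue/air interface.
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def robin_coefficient_from_index(refractive_index: float) -> float:
    """Boundary reflection parameter A = (1 + R_eff)/(1 - R_eff)."""
    r = _effective_reflection(refractive_index)
    return (1.0 + r) / (1.0 - r)


@dataclass(frozen=True)
class PhysicsConstants:
    """Medium constants entering the frequency-domain diffusion equation.

    Parameters
    ----------
    refractive_index : float
        Refractive index of the medium (>= 1); default 1.33 (water-like
        tissue).
    robin_coefficient : float, optional
        Dimensionless boundary reflection parameter A of the Robin condition
        ``phi + 2 A D dphi/dn = 0``.  If not given it is derived from the
        refractive-index mismatch.
    """

    refractive_index: float = 1.33
    robin_coefficient: float = field(default=float("nan"))

    def __post_init__(self):
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")
        if np.isnan(self.robin_coefficient):
            object.__setattr__(
                self,
                "robin_coefficient",
                robin_coefficient_from_index(self.refractive_index),
            )
        if self.robin_coefficient <= 0:
            raise ValueError("robin_coefficient must be positive")

    @property
    def light_speed_medium(self) -> float:
        """Speed of light in the medium, mm/ns."""
        return C_VACUUM / self.refractive_index


def angular_frequency(frequency_mhz: float) -> float:
    """Convert a modulation frequency in MHz to rad/ns."""
    return 2.0 * np.pi * frequency_mhz * 1e-3


def diffusion_coefficient(mu_a, mu_s_prime):
    """Diffusion coefficient D = 1 / (3 (mu_a + mu_s')), in mm.

    Both arguments may be scalars or arrays; they must be positive (a zero
    absorption with positive scattering is allowed as the degenerate
    scattering-only case).
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_a < 0) or np.any(mu_s_prime <= 0):
        raise ValueError("optical coefficients must be positive")
    out = 1.0 / (3.0 * (mu_a + mu_s_prime))
    if out.ndim == 0:
        return float(out)
    return out
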