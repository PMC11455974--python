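"""Dual-Cauchy (double-Lorentzian) model of cone density topography.

Human cone density features a steep foveal peak over a shallow peripheral
falloff; the sum of two zero-centred Cauchy kernels captures both regimes
and, unlike exponential or power-law fits, extends naturally to a bivariate
surface with different horizontal and vertical falloff widths:

    D_m(x) = A1·γ1m² / (x² + γ1m²) + A2·γ2m² / (x² + γ2m²),   m ∈ {h, v}

with the amplitudes (A1, A2) shared between the meridians so both reach the
same central peak, D(0) = A1 + A2, while the widths γ differ per meridian.
The bivariate surface replaces x²/γm² by the elliptical form
x²/γh² + y²/γv² in each component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DualCauchyProfile"]


@dataclass(frozen=True)
class DualCauchyProfile:
    """Amplitude-linked dual-Cauchy density profile.

    Amplitudes are in cones/mm² and widths in mm; component 1 is
    conventionally the narrower (foveal) one but no ordering is enforced.
    """

    a1: float
    a2: float
    gamma1_h: float
    gamma2_h: float
    gamma1_v: float
    gamma2_v: float

    def __post_init__(self) -> None:
        for name in ("gamma1_h", "gamma2_h", "gamma1_v", "gamma2_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def peak_density(self) -> float:
        """Central (peak) density, cones/mm²."""
        return self.a1 + self.a2

    def meridian_density(self, ecc_mm, meridian: str = "horizontal"):
        """Density along one meridian at eccentricity ``ecc_mm`` (mm)."""
        x = np.asarray(ecc_mm, dtype=np.float64)
        if meridian in ("horizontal", "nasal", "temporal"):
            g1, g2 = self.gamma1_h, self.gamma2_h
        elif meridian in ("vertical", "superior", "inferior"):
            g1, g2 = self.gamma1_v, self.gamma2_v
        else:
            raise ValueError(f"unknown meridian {meridian!r}")
        return (
            self.a1 * g1**2 / (x**2 + g1**2)
            + self.a2 * g2**2 / (x**2 + g2**2)
        )

    def density(self, x_mm, y_mm):
        """Bivariate density surface at retinal position (x, y) in mm."""
        x = np.asarray(x_mm, dtype=np.float64)
        y = np.asarray(y_mm, dtype=np.float64)
        q1 = x**2 / self.gamma1_h**2 + y**2 / self.gamma1_v**2
        q2 = x**2 / self.gamma2_h**2 + y**2 / self.gamma2_v**2
        return self.a1 / (1.0 + q1) + self.a2 / (1.0 + q2)
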