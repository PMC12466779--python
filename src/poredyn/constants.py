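"""Physical constants and spectrometer context.

All internal frequencies are angular (rad/s).  Interfaces that accept Hz
convert once on construction.  Gyromagnetic ratios are CODATA values; the
shielded/unshielded distinction is irrelevant at the 4-digit level used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi

#: reduced Planck constant, J s
HBAR = 1.054571817e-34
#: vacuum-permeability prefactor mu0/(4 pi), T^2 m^3 / J
MU0_OVER_4PI = 1.0e-7
#: Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

#: gyromagnetic ratios, rad s^-1 T^-1 (CODATA; 31P from gamma/2pi = 17.235 MHz/T)
GAMMA = {
    "1H": 2.6752218744e8,
    "13C": 6.728284e7,
    "31P": 1.08291e8,
}


@dataclass(frozen=True)
class PhysicalConstants:
    """Container for the constants entering dipolar coupling calculations."""

    hbar: float = HBAR
    mu0_over_4pi: float = MU0_OVER_4PI
    avogadro: float = AVOGADRO
    gamma: dict = field(default_factory=lambda: dict(GAMMA))

    def __post_init__(self) -> None:
        if self.hbar <= 0 or self.mu0_over_4pi <= 0 or self.avogadro <= 0:
            raise ValueError("physical constants must be strictly positive")
        for nuc, g in self.gamma.items():
            if g <= 0:
                raise ValueError(f"gyromagnetic ratio for {nuc} must be positive")

    def gamma_of(self, nuclide: str) -> float:
        try:
            return self.gamma[nuclide]
        except KeyError:
            known = ", ".join(sorted(self.gamma))
            raise KeyError(
                f"unknown nuclide {nuclide!r}; known nuclides: {known}"
            ) from None


@dataclass(frozen=True)
class SpectrometerContext:
    """Static field plus the angular frequencies entering the rate expressions.

    Parameters
    ----------
    b0 : float
        Static magnetic field in tesla.
    omega1 : float
        Spin-lock amplitude omega_1 in rad/s.  Default corresponds to the
        10 kHz spin-locking field used for rotating-frame relaxation.
    constants : PhysicalConstants
    """

    b0: float = 14.1
    omega1: float = TWO_PI * 1.0e4
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("static field must be positive")
        if self.omega1 < 0:
            raise ValueError("spin-lock amplitude must be non-negative")

    @classmethod
    def from_proton_mhz(cls, nu_h_mhz: float, omega1_hz: float = 1.0e4,
                        constants: PhysicalConstants | None = None) -> "SpectrometerContext":
        """Build a context from the 1H Larmor frequency in MHz."""
        constants = constants or PhysicalConstants()
        b0 = TWO_PI * nu_h_mhz * 1e6 / constants.gamma_of("1H")
        return cls(b0=b0, omega1=TWO_PI * omega1_hz, constants=constants)

    def omega(self, nuclide: str) -> float:
        """Larmor angular frequency gamma * B0, rad/s."""
        return self.constants.gamma_of(nuclide) * self.b0

    def larmor_mhz(self, nuclide: str) -> float:
        return self.omega(nuclide) / TWO_PI / 1e6


def default_context() -> SpectrometerContext:
    """The study's 14.1 T context, anchored to the printed 599.1 MHz 1H frequency."""
    return SpectrometerContext.from_proton_mhz(599.1)
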