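"""Physical constants and spin properties used throughout the package.

Gyromagnetic ratios are CODATA values in rad s^-1 T^-1.  The electron value
is stored as a magnitude: every place it enters the models is a |omega| inside
a Lorentzian, so the sign is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

HBAR = 1.054571817e-34  # J s
K_B = 1.380649e-23  # J K^-1

GAMMA_H = 2.6752218708e8  # 1H, rad s^-1 T^-1
GAMMA_C = 6.728284e7  # 13C
GAMMA_D = 4.1066279e7  # 2H (deuteron)
GAMMA_E = 1.76085963023e11  # electron, magnitude


@dataclass(frozen=True)
class SpinConstants:
    """Bundle of spin constants for the nuclei/electron entering the rate laws.

    ``I_H`` and ``I_D`` are the nuclear spin quantum numbers of 1H (1/2) and
    2H (1); they enter the dipolar deuteration scaling I(I+1)-weighted.
    """

    gamma_H: float = GAMMA_H
    gamma_C: float = GAMMA_C
    gamma_D: float = GAMMA_D
    gamma_e: float = GAMMA_E
    I_H: float = 0.5
    I_D: float = 1.0
    hbar: float = HBAR
    k_B: float = K_B

    def __post_init__(self) -> None:
        for name in ("gamma_H", "gamma_C", "gamma_D", "gamma_e", "hbar", "k_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive magnitude")

    @property
    def codata_consistent(self) -> bool:
        """True when the ratios match the physical isotopes within 0.1%.

        gamma_H/gamma_C ~ 3.976 and (gamma_H/gamma_D)^2 ~ 42.44.  Kept as a
        check rather than a constructor constraint so hypothetical isotope
        combinations (e.g. the identity case of the deuteration factor) can
        still be expressed.
        """
        return (
            abs(self.gamma_H / self.gamma_C - 3.976) / 3.976 < 1e-3
            and abs((self.gamma_H / self.gamma_D) ** 2 - 42.44) / 42.44 < 1e-3
        )


#: Default CODATA-grade constants.
DEFAULT_CONSTANTS = SpinConstants()
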