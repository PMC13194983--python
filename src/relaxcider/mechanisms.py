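"""Closed-form field-dependent relaxation-rate laws for each mechanism.

Longitudinal relaxation of the [1-13C]pyruvate carboxylate carbon is modeled
as a sum of independent additive channels:

* chemical shift anisotropy (CSA), quadratic in B0 in the extreme-narrowing
  regime: R1 = (2/15) (B0 * d_sigma * gamma_C)^2 * tau_c;
* paramagnetic relaxation enhancement (PRE) from dissolved O2, trace metal
  cations, or the DNP radical, modeled as a two-Lorentzian dipolar dispersion
  dominated by the electron Larmor frequency;
* field-independent dipolar channels (intra-molecular methyl 1H-13C and
  inter-molecular solvent 1H-13C), both in extreme narrowing;
* a lumped field-independent background (residual 2H-13C dipolar couplings,
  spin-rotation, ...).

Fast chemical exchange between the keto (Py) and hydrated gem-diol (PyH)
forms averages the two species' rates with their population fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .constants import DEFAULT_CONSTANTS, SpinConstants

if TYPE_CHECKING:  # pragma: no cover
    from .samples import GroundTruthRegistry, SampleComposition

__all__ = [
    "CSAParams",
    "PREParams",
    "DipolarParams",
    "ExchangeWeights",
    "r1_csa",
    "r1_pre",
    "deuteration_factor",
    "exchange_weighted_rate",
    "thermal_polarization",
    "total_r1",
    "scale_dipolar_to_temperature",
    "deuterated_limit_t1",
]


@dataclass
class CSAParams:
    """Chemical-shift-anisotropy channel: anisotropy (ppm) and rotational tau_c (s)."""

    delta_sigma: float  # ppm
    tau_c: float  # s

    def __post_init__(self) -> None:
        if self.delta_sigma < 0:
            raise ValueError("delta_sigma must be >= 0 ppm")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be > 0 s")

    def extreme_narrowing_ok(self, B_max: float, gamma: float = DEFAULT_CONSTANTS.gamma_C) -> bool:
        """True if omega*tau_c < 0.1 at the largest field used (fast-motion validity)."""
        return abs(gamma) * B_max * self.tau_c < 0.1


@dataclass
class PREParams:
    """Paramagnetic channel: zero-field amplitude (s^-1) and electron-nucleus tau_c (s).

    If both ``concentration`` (uM) and ``molar_relaxivity`` (s^-1 uM^-1) are
    given they must reproduce the amplitude; usually only the amplitude is
    known (dispersion fits return amplitude and tau_c).
    """

    amplitude_zero_field: float  # s^-1
    tau_c: float  # s
    concentration: Optional[float] = None  # uM
    molar_relaxivity: Optional[float] = None  # s^-1 uM^-1

    def __post_init__(self) -> None:
        if self.amplitude_zero_field < 0:
            raise ValueError("PRE amplitude must be >= 0")
        if self.tau_c <= 0:
            raise ValueError("PRE tau_c must be > 0")
        if self.concentration is not None and self.molar_relaxivity is not None:
            implied = self.concentration * self.molar_relaxivity
            if abs(implied - self.amplitude_zero_field) > 1e-9:
                raise ValueError(
                    "concentration x molar_relaxivity inconsistent with amplitude"
                )


@dataclass
class DipolarParams:
    """Field-independent dipolar channel, rate for the fully protonated case."""

    rate_protonated: float  # s^-1
    channel: str = "intra"  # "intra" | "inter"

    def __post_init__(self) -> None:
        if self.rate_protonated < 0:
            raise ValueError("dipolar rate must be >= 0")
        if self.channel not in ("intra", "inter"):
            raise ValueError("channel must be 'intra' or 'inter'")


@dataclass
class ExchangeWeights:
    """Population fractions of the keto (Py) and hydrated (PyH) forms."""

    p_Py: float = 10.0 / 11.0
    p_PyH: float = 1.0 / 11.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_Py <= 1.0 and 0.0 <= self.p_PyH <= 1.0):
            raise ValueError("population fractions must lie in [0, 1]")
        if abs(self.p_Py + self.p_PyH - 1.0) > 1e-12:
            raise ValueError("population fractions must sum to 1")


def r1_csa(B, csa: CSAParams, gamma: float = DEFAULT_CONSTANTS.gamma_C):
    """CSA relaxation rate (s^-1) at field ``B`` (T), extreme-narrowing form.

    R1 = (2/15) * (B * d_sigma * 1e-6 * gamma)^2 * tau_c.  Vectorized over B.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("B must be >= 0 T")
    rate = (2.0 / 15.0) * (B * csa.delta_sigma * 1e-6 * gamma) ** 2 * csa.tau_c
    return rate if rate.ndim else float(rate)


def _lorentzian(omega, tau_c: float):
    return 1.0 / (1.0 + (omega * tau_c) ** 2)


def r1_pre(
    B,
    pre: PREParams,
    gamma_I: float = DEFAULT_CONSTANTS.gamma_C,
    gamma_S: float = DEFAULT_CONSTANTS.gamma_e,
):
    """PRE rate (s^-1) at field ``B`` (T): two-Lorentzian dipolar dispersion.

    R1 = A * [0.3 / (1 + (gamma_I B tau_c)^2) + 0.7 / (1 + (gamma_S B tau_c)^2)],
    a simplified Solomon-Bloembergen form with a single correlation time whose
    dispersion is dominated by the electron Larmor frequency.  Equals the
    zero-field amplitude at B = 0 and is non-increasing in B.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("B must be >= 0 T")
    rate = pre.amplitude_zero_field * (
        0.3 * _lorentzian(abs(gamma_I) * B, pre.tau_c)
        + 0.7 * _lorentzian(abs(gamma_S) * B, pre.tau_c)
    )
    return rate if rate.ndim else float(rate)


def deuteration_factor(constants: SpinConstants = DEFAULT_CONSTANTS) -> float:
    """Dipolar rate reduction when 1H is replaced by 2H.

    (I_H (I_H + 1)) / (I_D (I_D + 1)) * (gamma_H / gamma_D)^2 ~ 15.9.
    """
    spin_ratio = (constants.I_H * (constants.I_H + 1)) / (
        constants.I_D * (constants.I_D + 1)
    )
    return spin_ratio * (constants.gamma_H / constants.gamma_D) ** 2


def exchange_weighted_rate(w: ExchangeWeights, r_py: float, r_pyh: float) -> float:
    """Observed rate under fast Py/PyH exchange: p_Py * R1_Py + p_PyH * R1_PyH."""
    return w.p_Py * r_py + w.p_PyH * r_pyh


def thermal_polarization(
    gamma: float, B: float, T: float, constants: SpinConstants = DEFAULT_CONSTANTS
) -> float:
    """Thermal-equilibrium polarization tanh(hbar*gamma*B / (2*k_B*T)) of a spin-1/2."""
    if B < 0:
        raise ValueError("B must be >= 0 T")
    if T <= 0:
        raise ValueError("T must be > 0 K")
    return math.tanh(constants.hbar * abs(gamma) * B / (2.0 * constants.k_B * T))


def total_r1(B, composition: "SampleComposition", registry: "GroundTruthRegistry"):
    """Total longitudinal rate (s^-1) at field ``B`` for a sample composition.

    Sum of the active mechanism rates; see
    :meth:`relaxcider.samples.GroundTruthRegistry.mechanism_rates` for the
    activation rules (degassing removes PRE:O2, chelators remove PRE:M+,
    deuteration divides the dipolar channels by the deuteration factor, ...).
    """
    terms = registry.mechanism_rates(B, composition)
    return sum(terms.values())


def scale_dipolar_to_temperature(
    rate_inter: float, rate_intra: float, T: float
) -> tuple[float, float]:
    """Apply the printed endpoint temperature factors to the dipolar rates.

    At 353 K the inter-molecular dipolar rate drops 2.6-fold and the
    intra-molecular one 2.8-fold relative to 293 K; only these two endpoint
    temperatures are supported (no interpolation is attempted).
    """
    if T == 293.0:
        return rate_inter, rate_intra
    if T == 353.0:
        return rate_inter / 2.6, rate_intra / 2.8
    raise ValueError("only the endpoint temperatures 293 K and 353 K are supported")


def deuterated_limit_t1(
    rate_inter_protonated: float,
    rate_intra_protonated: float,
    T: float = 293.0,
    constants: SpinConstants = DEFAULT_CONSTANTS,
) -> float:
    """Limiting T1 (s) of a fully deuterated system relaxing only via dipolar channels.

    Scales the protonated inter/intra rates to temperature ``T`` (endpoints
    only), divides by the deuteration factor and inverts the sum.
    """
    inter, intra = scale_dipolar_to_temperature(
        rate_inter_protonated, rate_intra_protonated, T
    )
    f = deuteration_factor(constants)
    return 1.0 / ((inter + intra) / f)
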