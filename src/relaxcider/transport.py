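"""Polarization loss along a field-time trajectory, SNR gains, polarization.

During transfer from the polarizer to the spectrometer the sample traverses
low fields where T1 can be short; the surviving polarization fraction is

    P(t)/P(0) = exp(-int_0^t dt' / T1(B(t'))).

The integral is evaluated with adaptive quadrature against a T1(B) model —
either the fitted additive mechanism model for a sample composition or a
tabulated dispersion curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import quad

from .constants import DEFAULT_CONSTANTS, SpinConstants
from .errors import DataError, InvalidParameterError
from .mechanisms import thermal_polarization, total_r1
from .profiles import NMRDProfile
from .samples import GroundTruthRegistry, SampleComposition

__all__ = [
    "FieldTimeProfile",
    "RelaxationMap",
    "retained_polarization",
    "snr_gain",
    "polarization_from_reference",
    "constant_field_profile",
    "example_ramp_profile",
]


@dataclass
class FieldTimeProfile:
    """Piecewise-linear B(t) trajectory (t in s strictly increasing, B > 0 in T)."""

    time: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.time.shape != self.B.shape or self.time.size < 2:
            raise InvalidParameterError("profile needs matching time/B arrays, >= 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.B <= 0):
            raise InvalidParameterError("B must be > 0 T everywhere")

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0])

    def field_at(self, t):
        return np.interp(t, self.time, self.B)


def constant_field_profile(B: float, duration: float) -> FieldTimeProfile:
    """Constant-field hold (the low-field shorthand for a transfer)."""
    return FieldTimeProfile(np.array([0.0, duration]), np.array([B, B]))


def example_ramp_profile(duration: float = 60.0) -> FieldTimeProfile:
    """Synthetic example trajectory: 1 mT hold, ramp to 1 T, ramp to 9.4 T.

    A stand-in for a measured polarizer-to-magnet field map (which is
    installation specific); thirds of the duration are spent in each segment.
    """
    t = np.array([0.0, duration / 3, 2 * duration / 3, duration])
    B = np.array([1e-3, 1e-3, 1.0, 9.4])
    return FieldTimeProfile(t, B)


class RelaxationMap:
    """T1(B) model: either a fitted additive composition model or a tabulated curve.

    Tabulated curves are interpolated linearly in log10(B) on rates, and held
    constant outside the tabulated range.
    """

    def __init__(
        self,
        composition: Optional[SampleComposition] = None,
        registry: Optional[GroundTruthRegistry] = None,
        curve: Optional[NMRDProfile] = None,
        table: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
    ):
        if composition is not None:
            self._registry = registry if registry is not None else GroundTruthRegistry()
            self._composition = composition
            self._logB = self._rates = None
        else:
            if curve is not None:
                B, t1 = curve.fields, curve.t1
            elif table is not None:
                B, t1 = np.asarray(table[0], float), np.asarray(table[1], float)
            else:
                raise InvalidParameterError(
                    "RelaxationMap needs a composition or a tabulated T1(B) curve"
                )
            if np.any(B <= 0) or np.any(t1 <= 0):
                raise InvalidParameterError("tabulated curve must have B > 0 and T1 > 0")
            order = np.argsort(B)
            self._logB = np.log10(B[order])
            self._rates = 1.0 / t1[order]
            self._composition = self._registry = None

    def r1(self, B):
        """Relaxation rate (s^-1) at field(s) B."""
        B = np.asarray(B, dtype=float)
        if self._composition is not None:
            return total_r1(B, self._composition, self._registry)
        return np.interp(np.log10(B), self._logB, self._rates)

    def t1(self, B):
        return 1.0 / self.r1(B)


def retained_polarization(
    relaxation: Union[RelaxationMap, float],
    profile: Optional[FieldTimeProfile] = None,
    duration: Optional[float] = None,
) -> float:
    """Fraction of polarization surviving ``duration`` along the field profile.

    exp(-int dt / T1(B(t))), adaptive quadrature at 1e-8 relative tolerance.
    ``relaxation`` may be a constant T1 (s) as shorthand; then the closed
    form exp(-duration/T1) is returned.  With a profile, ``duration`` defaults
    to the full profile span and must not exceed it.
    """
    if isinstance(relaxation, (int, float)):
        if relaxation <= 0:
            raise InvalidParameterError("T1 must be > 0")
        if duration is None:
            raise InvalidParameterError("constant-T1 shorthand needs a duration")
        return math.exp(-duration / float(relaxation))

    if profile is None:
        raise InvalidParameterError("retained_polarization needs a field-time profile")
    t0 = float(profile.time[0])
    if duration is None:
        duration = profile.span
    if duration > profile.span * (1.0 + 1e-12):
        raise InvalidParameterError("duration exceeds the field profile span")

    def integrand(t):
        r = relaxation.r1(profile.field_at(t))
        if not np.all(np.isfinite(r)) or np.any(np.asarray(r) < 0):
            raise DataError("T1(B) model is invalid (non-positive) on the path")
        return r

    breakpoints = profile.time[(profile.time > t0) & (profile.time < t0 + duration)]
    integral, _ = quad(
        integrand, t0, t0 + duration,
        points=list(breakpoints) if len(breakpoints) else None,
        epsrel=1e-8, epsabs=0.0, limit=200,
    )
    return math.exp(-integral)


def snr_gain(p_optimized: float, p_reference: float) -> float:
    """SNR ratio between two retained-polarization fractions."""
    if not 0.0 < p_reference <= 1.0 or not 0.0 < p_optimized <= 1.0:
        raise InvalidParameterError("polarization fractions must lie in (0, 1]")
    return p_optimized / p_reference


def polarization_from_reference(
    S_hyper: float,
    S_thermal: float,
    n_thermal_scans: int = 1,
    gamma: float = DEFAULT_CONSTANTS.gamma_C,
    B: float = 1.0,
    T: float = 293.0,
    constants: SpinConstants = DEFAULT_CONSTANTS,
) -> float:
    """Liquid-state polarization (percent) from a thermal reference spectrum.

    P = (S_hyper / (S_thermal / n_scans)) * P_thermal(gamma, B, T) * 100,
    where the thermal reference is the signal of the same sample at thermal
    equilibrium in field B (averaged over ``n_thermal_scans``).
    """
    if S_thermal <= 0:
        raise DataError("thermal reference signal must be > 0")
    if n_thermal_scans < 1:
        raise InvalidParameterError("n_thermal_scans must be >= 1")
    enhancement = S_hyper / (S_thermal / n_thermal_scans)
    return enhancement * thermal_polarization(gamma, B, T, constants) * 100.0
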