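"""Estimation: decay fits, band statistics, profile subtraction, mechanism fits.

The decomposition workflow mirrors how the study isolates mechanisms: pairs
of NMRD profiles that differ in a single preparation feature are subtracted
in rate space (additive channels cancel except the toggled one), the isolated
dispersion is fitted with the corresponding closed-form model, and the fitted
channels are reassembled into a full additive model whose residuals against
every input profile quantify self-consistency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit

from .constants import DEFAULT_CONSTANTS
from .errors import (
    ConfigurationError,
    DataError,
    DegenerateModelError,
    FitError,
    PairingError,
    PlanValidationError,
)
from .mechanisms import CSAParams, PREParams, r1_csa, r1_pre
from .profiles import (
    DEFAULT_BANDS,
    BandStatistics,
    DecaySeries,
    FieldBand,
    NMRDProfile,
    RateDifferenceProfile,
)
from .samples import NINE_SAMPLES, GroundTruthRegistry, SampleComposition

__all__ = [
    "MonoExpFit",
    "HyperpolarizedFit",
    "CSAFit",
    "PREFit",
    "PlanEntry",
    "DEFAULT_PLAN",
    "DecompositionResult",
    "fit_monoexponential",
    "fit_hyperpolarized_decay",
    "band_statistics",
    "subtract_rate_profiles",
    "subtract_band_means",
    "fit_csa",
    "fit_pre",
    "decompose_study",
]


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

@dataclass
class MonoExpFit:
    T1: float  # s
    T1_sd: float  # s
    amplitude: float
    amplitude_sd: float
    offset: float = 0.0
    offset_sd: float = 0.0
    residuals: Optional[np.ndarray] = None


@dataclass
class HyperpolarizedFit:
    T1: float  # s
    T1_sd: float  # s
    apparent_T1: float  # s, before flip-angle correction
    rf_rate: float  # s^-1, -ln(cos a)/TR consumed by sampling
    unbounded: bool = False  # apparent rate did not exceed the RF rate


def fit_monoexponential(series: DecaySeries, with_offset: bool = False) -> MonoExpFit:
    """Least-squares fit of S(t) = S0 exp(-t/T1) (+ optional constant offset).

    SDs come from the Jacobian-based covariance of the fit.  Raises
    :class:`FitError` for fewer than 3 points, non-finite signals, or
    non-convergence.
    """
    n_params = 3 if with_offset else 2
    if len(series) < max(3, n_params + 1 if with_offset else 3):
        raise FitError(f"need >= 3 points for a mono-exponential fit, got {len(series)}")
    t = series.time
    s = series.signal
    if not np.all(np.isfinite(s)):
        raise FitError("signal contains non-finite values")

    scale = float(np.max(np.abs(s))) or 1.0
    # log-linear initial guess from the positive part of the decay
    pos = s > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(s[pos]), 1)[0]
        t1_guess = -1.0 / slope if slope < 0 else (t[-1] - t[0])
    else:
        t1_guess = t[-1] - t[0]
    t1_guess = float(np.clip(t1_guess, 1e-6, 1e8))

    if with_offset:
        def model(tt, a, t1, c):
            return a * np.exp(-tt / t1) + c
        p0 = [scale, t1_guess, 0.0]
    else:
        def model(tt, a, t1):
            return a * np.exp(-tt / t1)
        p0 = [scale, t1_guess]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, t, s, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitError(f"mono-exponential fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = s - model(t, *popt)
    if with_offset:
        return MonoExpFit(popt[1], perr[1], popt[0], perr[0], popt[2], perr[2], resid)
    return MonoExpFit(popt[1], perr[1], popt[0], perr[0], residuals=resid)


def fit_hyperpolarized_decay(
    series: DecaySeries,
    flip_angle: Optional[float] = None,
    repetition_time: Optional[float] = None,
) -> HyperpolarizedFit:
    """Flip-angle-corrected T1 from a hyperpolarized decay series.

    Repeated small-flip-angle sampling consumes polarization as
    cos^(n-1)(a), so the apparent decay rate exceeds 1/T1 by the RF rate
    -ln(cos a)/TR.  The series is fitted mono-exponentially and the RF rate
    is subtracted from the apparent rate.  When the apparent rate does not
    exceed the RF rate the T1 is unbounded: a warning is issued and the
    result flagged.
    """
    alpha = series.flip_angle if flip_angle is None else flip_angle
    tr = series.repetition_time if repetition_time is None else repetition_time
    if not 0.0 < alpha <= 90.0:
        raise DegenerateModelError(f"flip angle must be in (0, 90] deg, got {alpha}")
    if alpha >= 90.0 and len(series) > 1:
        raise DegenerateModelError("90 deg excitation leaves no signal for later points")
    if tr is None:
        diffs = np.diff(series.time)
        if diffs.size == 0:
            raise DataError("cannot infer repetition time from a single point")
        tr = float(diffs[0])
    else:
        diffs = np.diff(series.time)
    if diffs.size and not np.allclose(diffs, diffs[0], rtol=1e-6, atol=0.0):
        raise DataError("hyperpolarized decay fitting requires uniform sampling")

    rf_rate = -math.log(math.cos(math.radians(alpha))) / tr
    base = fit_monoexponential(
        DecaySeries(series.time - series.time[0], series.signal, alpha, tr)
    )
    apparent_rate = 1.0 / base.T1
    true_rate = apparent_rate - rf_rate
    if true_rate <= 0:
        warnings.warn(
            "apparent decay rate does not exceed the RF consumption rate; "
            "T1 is unbounded by these data",
            stacklevel=2,
        )
        return HyperpolarizedFit(math.inf, math.inf, base.T1, rf_rate, unbounded=True)
    rate_sd = base.T1_sd / base.T1**2
    return HyperpolarizedFit(1.0 / true_rate, rate_sd / true_rate**2, base.T1, rf_rate)


# ---------------------------------------------------------------------------
# band statistics and profile subtraction
# ---------------------------------------------------------------------------

def band_statistics(
    profile: NMRDProfile, bands: Sequence[FieldBand] = DEFAULT_BANDS
) -> List[BandStatistics]:
    """Unweighted mean T1 +/- sample SD per field band (empty bands flagged)."""
    out = []
    for band in bands:
        mask = band.contains(profile.fields)
        vals = profile.t1[mask]
        n = int(mask.sum())
        if n == 0:
            out.append(BandStatistics(band, None, None, 0))
        elif n == 1:
            out.append(BandStatistics(band, float(vals[0]), 0.0, 1, single_observation=True))
        else:
            out.append(
                BandStatistics(band, float(vals.mean()), float(vals.std(ddof=1)), n)
            )
    return out


def _interp_log_field(B_target, B_src, values):
    """Linear interpolation in log10(B)."""
    return np.interp(np.log10(B_target), np.log10(B_src), values)


def subtract_rate_profiles(
    a: NMRDProfile, b: NMRDProfile, interpolate: bool = False, label: str = ""
) -> RateDifferenceProfile:
    """Pointwise dR1(B) = 1/T1_a - 1/T1_b with SD propagation.

    Shared fields are matched exactly; with ``interpolate=True`` profile b's
    rates (and SDs) are interpolated linearly in log10(B) onto a's fields
    inside b's coverage.  sigma_dR = sqrt((s_a/T1_a^2)^2 + (s_b/T1_b^2)^2).
    """
    Ba, Bb = a.fields, b.fields
    if interpolate:
        mask = (Ba >= Bb.min()) & (Ba <= Bb.max())
        if not mask.any():
            raise PairingError(
                f"profiles {a.sample_id} and {b.sample_id} have disjoint field coverage"
            )
        B = Ba[mask]
        Ra = a.rates[mask]
        sa = a.rate_sd[mask]
        Rb = _interp_log_field(B, Bb, b.rates)
        sb = _interp_log_field(B, Bb, b.rate_sd)
    else:
        ia, ib = [], []
        for i, Bi in enumerate(Ba):
            j = int(np.argmin(np.abs(Bb - Bi)))
            if np.isclose(Bb[j], Bi, rtol=1e-9, atol=0.0):
                ia.append(i)
                ib.append(j)
        if not ia:
            raise PairingError(
                f"profiles {a.sample_id} and {b.sample_id} share no fields "
                "(enable interpolation?)"
            )
        B = Ba[ia]
        Ra, sa = a.rates[ia], a.rate_sd[ia]
        Rb, sb = b.rates[ib], b.rate_sd[ib]
    sd = np.sqrt(sa**2 + sb**2)
    return RateDifferenceProfile((a.sample_id, b.sample_id), B, Ra - Rb, sd, label=label)


def subtract_band_means(
    a: NMRDProfile, b: NMRDProfile, bands: Sequence[FieldBand] = DEFAULT_BANDS
) -> Dict[str, Tuple[float, float]]:
    """Per-band dR1 from band-mean T1s, SD propagated from the band SDs of the mean."""
    out: Dict[str, Tuple[float, float]] = {}
    for sa, sb in zip(band_statistics(a, bands), band_statistics(b, bands)):
        if sa.empty or sb.empty:
            continue
        dr = 1.0 / sa.mean_t1 - 1.0 / sb.mean_t1
        ea = (sa.sd_t1 / math.sqrt(sa.n)) / sa.mean_t1**2 if sa.sd_t1 else 0.0
        eb = (sb.sd_t1 / math.sqrt(sb.n)) / sb.mean_t1**2 if sb.sd_t1 else 0.0
        out[sa.band.name] = (dr, math.hypot(ea, eb))
    return out


# ---------------------------------------------------------------------------
# mechanism fits
# ---------------------------------------------------------------------------

@dataclass
class CSAFit:
    delta_sigma: float  # ppm
    delta_sigma_sd: float
    tau_c: float  # s (held fixed)
    baseline: float  # s^-1
    baseline_sd: float
    reduced_chi_square: float


@dataclass
class PREFit:
    params: PREParams
    amplitude_sd: float
    tau_c_sd: float
    tau_c_identifiable: bool
    reduced_chi_square: float


def _extract_rate_data(data: Union[NMRDProfile, RateDifferenceProfile]):
    if isinstance(data, NMRDProfile):
        return data.fields, data.rates, data.rate_sd
    return data.B0, data.delta_R1, data.delta_R1_sd


def _weights(sd: np.ndarray) -> Optional[np.ndarray]:
    """1/sigma weights; missing SDs get the median SD; all-missing/zero -> None."""
    sd = np.asarray(sd, dtype=float)
    finite = np.isfinite(sd) & (sd > 0)
    if not finite.any():
        return None
    out = sd.copy()
    out[~finite] = np.median(sd[finite])
    return out


def fit_csa(
    data: Union[NMRDProfile, RateDifferenceProfile],
    tau_c: Optional[float],
    gamma: float = DEFAULT_CONSTANTS.gamma_C,
    baseline: Optional[float] = None,
    B_min: float = 1.0,
) -> CSAFit:
    """Fit baseline + (2/15)(B ds 1e-6 gamma)^2 tau_c to the high-field rates.

    tau_c must be supplied (ds and tau_c are not jointly identifiable from
    quadratic-in-B data); the fit is linear in B^2 so it is solved by weighted
    linear least squares.  ``baseline`` fixes the field-independent offset;
    by default it is a free parameter.
    """
    if tau_c is None or tau_c <= 0:
        raise ConfigurationError("fit_csa requires a positive tau_c (e.g. MD-derived)")
    B, R, sd = _extract_rate_data(data)
    mask = B >= B_min
    if mask.sum() < 3:
        raise DataError(
            f"need >= 3 points with B >= {B_min} T for the CSA fit, got {int(mask.sum())}"
        )
    B, R, sd = B[mask], R[mask], sd[mask]
    sigma = _weights(sd)
    w = 1.0 / sigma**2 if sigma is not None else np.ones_like(R)

    x = B**2
    if baseline is None:
        A = np.column_stack([np.ones_like(x), x])
        y = R
    else:
        A = x[:, None]
        y = R - baseline
    Aw = A * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    resid = y - A @ coef
    dof = max(len(y) - A.shape[1], 1)
    chi2 = float(np.sum(w * resid**2))
    redchi = chi2 / dof
    cov = np.linalg.inv(Aw.T @ Aw)
    if sigma is None:
        cov = cov * (np.sum(resid**2) / dof)
    if baseline is None:
        b0, k = coef
        b0_sd = math.sqrt(max(cov[0, 0], 0.0))
        k_sd = math.sqrt(max(cov[1, 1], 0.0))
    else:
        (k,) = coef
        b0, b0_sd = baseline, 0.0
        k_sd = math.sqrt(max(cov[0, 0], 0.0))

    # k = (2/15) (ds * 1e-6 * gamma)^2 tau_c  ->  ds = sqrt(7.5 k / tau_c) / (1e-6 g)
    g6 = 1e-6 * abs(gamma)
    if k > 0:
        ds = math.sqrt(7.5 * k / tau_c) / g6
        ds_sd = k_sd * ds / (2.0 * k)
    else:
        ds = 0.0
        ds_sd = math.sqrt(7.5 * max(k_sd, 0.0) / tau_c) / g6
    return CSAFit(ds, ds_sd, tau_c, float(b0), float(b0_sd), redchi)


_TAU_GRID = (1e-12, 1e-11, 1e-10, 1e-9)


def fit_pre(
    difference: Union[RateDifferenceProfile, NMRDProfile],
    gamma_I: float = DEFAULT_CONSTANTS.gamma_C,
    gamma_S: float = DEFAULT_CONSTANTS.gamma_e,
    molar_relaxivity: Optional[float] = None,
) -> PREFit:
    """Fit the two-Lorentzian PRE dispersion (amplitude, tau_c) to a rate profile.

    tau_c is grid-initialized over {1, 10, 100, 1000} ps and the restart with
    the lowest reduced chi-square (ties: smallest tau_c) is kept.  Flat data
    leave tau_c flagged unidentifiable rather than raising.  ``concentration``
    is populated on the returned params only when a molar relaxivity is
    supplied.
    """
    B, R, sd = _extract_rate_data(difference)
    if len(B) < 4:
        raise DataError(f"need >= 4 points for a PRE fit, got {len(B)}")
    if B.max() / B.min() < 10.0:
        raise DataError("PRE fit needs at least one decade of field coverage")
    sigma = _weights(sd)
    noise = np.median(sigma) if sigma is not None else max(np.std(R), 1e-12)
    if np.mean(R) < -2.0 * noise / math.sqrt(len(R)):
        raise DataError("mean rate difference is negative beyond noise")

    # tau is fitted in picoseconds so both parameters are O(1)-scaled for the
    # trust-region solver; converted back at the end.
    def model(BB, amp, tau_ps):
        tau = tau_ps * 1e-12
        return amp * (
            0.3 / (1.0 + (abs(gamma_I) * BB * tau) ** 2)
            + 0.7 / (1.0 + (abs(gamma_S) * BB * tau) ** 2)
        )

    amp0 = max(float(np.max(R)), 1e-12)
    best = None
    for tau0 in _TAU_GRID:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, B, R, p0=[amp0, tau0 * 1e12],
                    sigma=sigma, absolute_sigma=sigma is not None,
                    bounds=([0.0, 1e-2], [np.inf, 1e6]),
                    x_scale=[amp0, tau0 * 1e12],
                    maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
        except RuntimeError:
            continue
        resid = R - model(B, *popt)
        w = 1.0 / sigma**2 if sigma is not None else np.ones_like(R)
        redchi = float(np.sum(w * resid**2)) / max(len(R) - 2, 1)
        cand = (redchi, popt[1], popt, pcov)
        if best is None or (cand[0], cand[1]) < (best[0] * (1 + 1e-9), best[1]):
            best = cand
    if best is None:
        raise FitError("PRE dispersion fit did not converge from any restart")
    redchi, _, popt, pcov = best
    amp, tau = float(popt[0]), float(popt[1]) * 1e-12
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    amp_sd, tau_sd = float(perr[0]), float(perr[1]) * 1e-12

    # tau_c is unidentifiable when there is no resolvable dispersion: either
    # the amplitude is consistent with zero or the model varies less than the
    # noise across the measured field range.
    span = float(
        model(np.array([B.min()]), amp, tau * 1e12)[0]
        - model(np.array([B.max()]), amp, tau * 1e12)[0]
    )
    identifiable = bool(amp > 2.0 * amp_sd and span > noise * 0.5 and np.isfinite(tau_sd))
    conc = None
    if molar_relaxivity is not None and molar_relaxivity > 0:
        conc = amp / molar_relaxivity
    params = PREParams(amp, tau, concentration=conc, molar_relaxivity=molar_relaxivity)
    return PREFit(params, amp_sd, tau_sd, identifiable, redchi)


# ---------------------------------------------------------------------------
# study decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanEntry:
    """One subtraction: rate(minuend) - rate(subtrahend) isolates ``mechanism``."""

    minuend: str
    subtrahend: str
    mechanism: str
    allow_multifeature: bool = False


#: Default ledger: intraDD from #B-#A (methyl deuteration toggled), interDD
#: from #E-#D (solvent toggled), PRE:O2 from #D-#B (degassing toggled),
#: PRE:M+ from #I-#F (Tris toggled) and #H-#D (the D2O series has no
#: single-feature chelator pair, hence the override).
DEFAULT_PLAN: Tuple[PlanEntry, ...] = (
    PlanEntry("B", "A", "intra_dd"),
    PlanEntry("E", "D", "inter_dd"),
    PlanEntry("D", "B", "pre_o2"),
    PlanEntry("I", "F", "pre_metal_h2o"),
    PlanEntry("H", "D", "pre_metal_d2o", allow_multifeature=True),
)


@dataclass
class DecompositionResult:
    """Fitted mechanism parameters, the assembled registry, and residuals."""

    background: float
    background_sd: float
    intra_dd_delta: float
    intra_dd_sd: float
    inter_dd_delta: float
    inter_dd_sd: float
    pre_o2: Optional[PREFit]
    pre_metal_h2o: Optional[PREFit]
    pre_metal_d2o: Optional[PREFit]
    csa: CSAFit
    radical: Optional[PREFit]
    registry: GroundTruthRegistry
    residuals: Dict[str, np.ndarray]  # per-profile R1_model - R1_obs
    relative_residuals: Dict[str, np.ndarray]
    reduced_chi_square: float
    plan: Tuple[PlanEntry, ...]

    @property
    def rms_relative_residual(self) -> float:
        all_rel = np.concatenate(list(self.relative_residuals.values()))
        return float(np.sqrt(np.mean(all_rel**2)))

    def to_dict(self) -> dict:
        def prefit(p: Optional[PREFit]):
            if p is None:
                return None
            return {
                "amplitude_s-1": p.params.amplitude_zero_field,
                "amplitude_sd": p.amplitude_sd,
                "tau_c_s": p.params.tau_c,
                "tau_c_sd": p.tau_c_sd,
                "tau_c_identifiable": p.tau_c_identifiable,
                "concentration_uM": p.params.concentration,
                "reduced_chi_square": p.reduced_chi_square,
            }

        return {
            "background_s-1": {"value": self.background, "sd": self.background_sd},
            "intra_dd_s-1": {"value": self.intra_dd_delta, "sd": self.intra_dd_sd},
            "inter_dd_s-1": {"value": self.inter_dd_delta, "sd": self.inter_dd_sd},
            "pre_o2": prefit(self.pre_o2),
            "pre_metal_h2o": prefit(self.pre_metal_h2o),
            "pre_metal_d2o": prefit(self.pre_metal_d2o),
            "csa": {
                "delta_sigma_ppm": self.csa.delta_sigma,
                "delta_sigma_sd": self.csa.delta_sigma_sd,
                "tau_c_s": self.csa.tau_c,
                "baseline_s-1": self.csa.baseline,
            },
            "radical": prefit(self.radical),
            "rms_relative_residual": self.rms_relative_residual,
            "reduced_chi_square": self.reduced_chi_square,
            "plan": [
                {"minuend": e.minuend, "subtrahend": e.subtrahend, "mechanism": e.mechanism}
                for e in self.plan
            ],
            "residuals": {
                sid: {"delta_R1_s-1": r.tolist()} for sid, r in self.residuals.items()
            },
        }


def _weighted_mean(values: np.ndarray, sd: np.ndarray) -> Tuple[float, float]:
    sigma = _weights(sd)
    if sigma is None:
        n = len(values)
        return float(np.mean(values)), float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    w = 1.0 / sigma**2
    mean = float(np.sum(w * values) / np.sum(w))
    return mean, float(math.sqrt(1.0 / np.sum(w)))


def decompose_study(
    profiles: Union[Mapping[str, NMRDProfile], Iterable[NMRDProfile]],
    plan: Sequence[PlanEntry] = DEFAULT_PLAN,
    registry_seeds: Optional[GroundTruthRegistry] = None,
    compositions: Mapping[str, SampleComposition] = NINE_SAMPLES,
    bands: Sequence[FieldBand] = DEFAULT_BANDS,
    background_sample: str = "A",
    radical_sample: Optional[str] = "G",
    csa_tau_c: Optional[float] = None,
    allow_multifeature: bool = False,
    interpolate: bool = False,
) -> DecompositionResult:
    """Execute the full mechanism decomposition over a set of NMRD profiles.

    Ledger: the field-independent background comes from the most-protected
    sample's low-field band; the dipolar differences from their single-toggle
    pairs; the PRE channels from dispersion fits to their pair differences;
    CSA from the high-field excess of the background sample (tau_c held at
    the registry seed); the radical term, if a radical sample is present, is
    fitted as the residual over the assembled radical-free model.  The
    assembled additive model is then evaluated against every input profile.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.sample_id: p for p in profiles}
    seeds = registry_seeds if registry_seeds is not None else GroundTruthRegistry()
    low_band = bands[0]

    # -- plan validation ----------------------------------------------------
    for entry in plan:
        for sid in (entry.minuend, entry.subtrahend):
            if sid not in profiles:
                raise PlanValidationError(f"plan references missing profile {sid!r}")
        ca, cb = compositions.get(entry.minuend), compositions.get(entry.subtrahend)
        if ca is not None and cb is not None:
            diff = ca.differing_features(cb)
            if len(diff) != 1 and not (entry.allow_multifeature or allow_multifeature):
                raise PlanValidationError(
                    f"pair ({entry.minuend}, {entry.subtrahend}) differs in "
                    f"{len(diff)} features {diff}; expected exactly one "
                    "(set allow_multifeature to override)"
                )

    # -- background from the most-protected sample's low band ---------------
    prof_bg = profiles[background_sample]
    mask = low_band.contains(prof_bg.fields)
    if not mask.any():
        raise DataError(f"no low-band points in background sample {background_sample}")
    background, background_sd = _weighted_mean(
        prof_bg.rates[mask], prof_bg.rate_sd[mask]
    )

    # -- pair subtractions ---------------------------------------------------
    diffs = {
        e.mechanism: subtract_rate_profiles(
            profiles[e.minuend], profiles[e.subtrahend],
            interpolate=interpolate, label=e.mechanism,
        )
        for e in plan
    }

    def band_mean_rate(diff: RateDifferenceProfile) -> Tuple[float, float]:
        m = low_band.contains(diff.B0)
        if not m.any():
            raise DataError(f"no low-band points in difference {diff.pair}")
        return _weighted_mean(diff.delta_R1[m], diff.delta_R1_sd[m])

    intra, intra_sd = band_mean_rate(diffs["intra_dd"]) if "intra_dd" in diffs else (0.0, 0.0)
    inter, inter_sd = band_mean_rate(diffs["inter_dd"]) if "inter_dd" in diffs else (0.0, 0.0)
    pre_o2 = fit_pre(diffs["pre_o2"]) if "pre_o2" in diffs else None
    pre_m_h2o = fit_pre(diffs["pre_metal_h2o"]) if "pre_metal_h2o" in diffs else None
    pre_m_d2o = fit_pre(diffs["pre_metal_d2o"]) if "pre_metal_d2o" in diffs else None

    # -- CSA from the high-field excess of the background sample ------------
    tau_rot = csa_tau_c if csa_tau_c is not None else seeds.csa.tau_c
    csa = fit_csa(prof_bg, tau_rot, seeds.constants.gamma_C)

    # -- assemble the fitted registry ----------------------------------------
    fitted = replace(
        seeds,
        background=background,
        intra_dd_delta=max(intra, 0.0),
        inter_dd_delta=max(inter, 0.0),
        pre_o2=pre_o2.params if pre_o2 else seeds.pre_o2,
        pre_metal_h2o=pre_m_h2o.params if pre_m_h2o else seeds.pre_metal_h2o,
        pre_metal_d2o=pre_m_d2o.params if pre_m_d2o else seeds.pre_metal_d2o,
        csa=CSAParams(csa.delta_sigma, tau_rot),
    )

    # -- radical as a residual over the radical-free model -------------------
    radical_fit = None
    if radical_sample is not None and radical_sample in profiles:
        comp = compositions[radical_sample]
        if comp.has_radical and not comp.radical_filtered:
            prof = profiles[radical_sample]
            no_radical = replace(comp, has_radical=False, radical_filtered=False)
            model_rates = np.array(
                [sum(fitted.mechanism_rates(b, no_radical).values()) for b in prof.fields]
            )
            excess = RateDifferenceProfile(
                (radical_sample, "model"), prof.fields,
                prof.rates - model_rates, prof.rate_sd, label="radical",
            )
            radical_fit = fit_pre(excess)
            fitted = replace(fitted, radical=radical_fit.params)

    # -- residuals of the assembled model vs every profile -------------------
    residuals: Dict[str, np.ndarray] = {}
    rel_residuals: Dict[str, np.ndarray] = {}
    chi2, ndata = 0.0, 0
    for sid, prof in profiles.items():
        comp = compositions.get(sid)
        if comp is None:
            continue
        model_rates = np.array(
            [sum(fitted.mechanism_rates(b, comp).values()) for b in prof.fields]
        )
        res = model_rates - prof.rates
        residuals[sid] = res
        rel_residuals[sid] = res / prof.rates
        sigma = _weights(prof.rate_sd)
        if sigma is not None:
            chi2 += float(np.sum((res / sigma) ** 2))
            ndata += len(res)
    n_params = 10
    redchi = chi2 / max(ndata - n_params, 1) if ndata else math.nan

    return DecompositionResult(
        background, background_sd, intra, intra_sd, inter, inter_sd,
        pre_o2, pre_m_h2o, pre_m_d2o, csa, radical_fit,
        fitted, residuals, rel_residuals, redchi, tuple(plan),
    )
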