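"""CSV / config / report I/O.

Fixed units throughout: tesla, seconds, s^-1, ppm, degrees, kelvin.  CSV
files use a decimal point, UTF-8 and LF newlines; floats are written with 12
significant digits so round trips are lossless at that precision.

Schemas
-------
NMRD CSV:        ``sample_id,B0_T,T1_s,T1_sd_s,n_obs`` (SD and n may be empty)
decay CSV:       ``time_s,signal,flip_angle_deg``
field profile:   ``time_s,B_T``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .mechanisms import CSAParams, PREParams
from .profiles import DecaySeries, FieldPoint, NMRDProfile
from .samples import GroundTruthRegistry
from .transport import FieldTimeProfile

__all__ = [
    "NMRD_HEADER",
    "read_nmrd_csv",
    "write_nmrd_csv",
    "read_decay_csv",
    "write_decay_csv",
    "read_field_profile_csv",
    "write_field_profile_csv",
    "registry_from_config",
    "registry_to_dict",
    "load_config",
    "write_json_report",
]

NMRD_HEADER = ["sample_id", "B0_T", "T1_s", "T1_sd_s", "n_obs"]
DECAY_HEADER = ["time_s", "signal", "flip_angle_deg"]
FIELD_PROFILE_HEADER = ["time_s", "B_T"]

_FMT = "%.12g"


def _check_header(path: Path, expected: List[str]) -> None:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    if header != expected:
        raise DataError(
            f"{path}: malformed header {header!r}, expected {','.join(expected)}"
        )


def read_nmrd_csv(path: Union[str, Path]) -> List[NMRDProfile]:
    """Parse NMRD profiles from CSV; rows grouped by sample_id, sorted by field.

    Blank ``T1_sd_s`` leaves the point's SD unset (the downstream median-SD
    weighting rule applies).  Non-positive B0 or T1 raise a parse error
    naming the offending row.
    """
    path = Path(path)
    _check_header(path, NMRD_HEADER)
    df = pd.read_csv(path, dtype={"sample_id": str})
    profiles: Dict[str, List[FieldPoint]] = {}
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        B0, T1 = float(row["B0_T"]), float(row["T1_s"])
        if B0 <= 0 or T1 <= 0 or not np.isfinite(B0) or not np.isfinite(T1):
            raise DataError(f"{path}: line {line_no}: non-positive B0 or T1")
        sd = row.get("T1_sd_s")
        sd = None if pd.isna(sd) else float(sd)
        n_obs = row.get("n_obs")
        n_obs = 1 if pd.isna(n_obs) else int(n_obs)
        try:
            point = FieldPoint(B0, T1, sd, n_obs)
        except ValueError as exc:
            raise DataError(f"{path}: line {line_no}: {exc}") from exc
        profiles.setdefault(str(row["sample_id"]), []).append(point)
    return [NMRDProfile(sid, pts) for sid, pts in profiles.items()]


def write_nmrd_csv(profiles: Sequence[NMRDProfile], path: Union[str, Path]) -> None:
    rows = []
    for prof in profiles:
        for p in prof.points:
            rows.append(
                {
                    "sample_id": prof.sample_id,
                    "B0_T": p.B0,
                    "T1_s": p.T1,
                    "T1_sd_s": p.T1_sd if p.T1_sd is not None else np.nan,
                    "n_obs": p.n_obs,
                }
            )
    df = pd.DataFrame(rows, columns=NMRD_HEADER)
    df.to_csv(path, index=False, float_format=_FMT, lineterminator="\n")


def read_decay_csv(path: Union[str, Path]) -> DecaySeries:
    path = Path(path)
    _check_header(path, DECAY_HEADER)
    df = pd.read_csv(path)
    if df["time_s"].size < 1:
        raise DataError(f"{path}: empty decay series")
    alphas = df["flip_angle_deg"].dropna().unique()
    if len(alphas) > 1:
        raise DataError(f"{path}: multiple flip angles in one series")
    alpha = float(alphas[0]) if len(alphas) else 90.0
    t = df["time_s"].to_numpy(float)
    tr = float(np.diff(t)[0]) if t.size >= 2 else None
    return DecaySeries(t, df["signal"].to_numpy(float), alpha, tr)


def write_decay_csv(series: DecaySeries, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "time_s": series.time,
            "signal": series.signal,
            "flip_angle_deg": series.flip_angle,
        }
    )
    df.to_csv(path, index=False, float_format=_FMT, lineterminator="\n")


def read_field_profile_csv(path: Union[str, Path]) -> FieldTimeProfile:
    path = Path(path)
    _check_header(path, FIELD_PROFILE_HEADER)
    df = pd.read_csv(path)
    return FieldTimeProfile(df["time_s"].to_numpy(float), df["B_T"].to_numpy(float))


def write_field_profile_csv(profile: FieldTimeProfile, path: Union[str, Path]) -> None:
    pd.DataFrame({"time_s": profile.time, "B_T": profile.B}).to_csv(
        path, index=False, float_format=_FMT, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# registry config
# ---------------------------------------------------------------------------

def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def registry_to_dict(reg: GroundTruthRegistry) -> dict:
    """Serializable view of the registry (units: s^-1, s, ppm)."""
    return {
        "mechanisms": {
            "background": {"rate": reg.background},
            "intraDD": {"rate": reg.intra_dd_delta},
            "interDD": {"rate": reg.inter_dd_delta},
            "pre_o2": {
                "amplitude": reg.pre_o2.amplitude_zero_field,
                "tau_c": reg.pre_o2.tau_c,
                "molar_relaxivity": reg.pre_o2.molar_relaxivity,
            },
            "pre_metal": {
                "amplitude_h2o": reg.pre_metal_h2o.amplitude_zero_field,
                "amplitude_d2o": reg.pre_metal_d2o.amplitude_zero_field,
                "tau_c": reg.pre_metal_h2o.tau_c,
            },
            "csa": {"delta_sigma": reg.csa.delta_sigma, "tau_c": reg.csa.tau_c},
            "radical": {
                "amplitude": reg.radical.amplitude_zero_field,
                "tau_c": reg.radical.tau_c,
            },
        },
        "provenance": dict(reg.provenance),
    }


def registry_from_config(config: Union[dict, str, Path, None]) -> GroundTruthRegistry:
    """Registry from a config mapping (or path); unspecified entries keep defaults."""
    if config is None:
        return GroundTruthRegistry()
    if not isinstance(config, dict):
        config = load_config(config)
    reg = GroundTruthRegistry()
    mech = config.get("mechanisms", {})
    kwargs: dict = {}
    if "background" in mech:
        kwargs["background"] = float(mech["background"]["rate"])
    if "intraDD" in mech:
        kwargs["intra_dd_delta"] = float(mech["intraDD"]["rate"])
    if "interDD" in mech:
        kwargs["inter_dd_delta"] = float(mech["interDD"]["rate"])
    if "pre_o2" in mech:
        m = mech["pre_o2"]
        kwargs["pre_o2"] = PREParams(
            float(m.get("amplitude", reg.pre_o2.amplitude_zero_field)),
            float(m.get("tau_c", reg.pre_o2.tau_c)),
            molar_relaxivity=m.get("molar_relaxivity"),
        )
    if "pre_metal" in mech:
        m = mech["pre_metal"]
        tau = float(m.get("tau_c", reg.pre_metal_h2o.tau_c))
        kwargs["pre_metal_h2o"] = PREParams(
            float(m.get("amplitude_h2o", reg.pre_metal_h2o.amplitude_zero_field)), tau
        )
        kwargs["pre_metal_d2o"] = PREParams(
            float(m.get("amplitude_d2o", reg.pre_metal_d2o.amplitude_zero_field)), tau
        )
    if "csa" in mech:
        m = mech["csa"]
        kwargs["csa"] = CSAParams(
            float(m.get("delta_sigma", reg.csa.delta_sigma)),
            float(m.get("tau_c", reg.csa.tau_c)),
        )
    if "radical" in mech:
        m = mech["radical"]
        kwargs["radical"] = PREParams(
            float(m.get("amplitude", reg.radical.amplitude_zero_field)),
            float(m.get("tau_c", reg.radical.tau_c)),
        )
    from dataclasses import replace

    return replace(reg, **kwargs) if kwargs else reg


def write_json_report(report: dict, path: Union[str, Path]) -> None:
    """Deterministic JSON (sorted keys, LF, no timestamps)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
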