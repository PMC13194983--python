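#!/usr/bin/env python
"""Isolate and fit the relaxation mechanisms by pairwise profile subtraction.

Executes the decomposition ledger — background from #A's low band, the
dipolar differences from the (#B,#A) and (#E,#D) toggles, the O2 and metal
paramagnetic dispersions from (#D,#B), (#I,#F) and (#H,#D), the chemical
shift anisotropy from #A's high-field excess, and the radical term as the
residual of #G — then reassembles the additive model and reports residuals
against all nine profiles.  Writes the full decomposition report as JSON and
a diagnostic figure.
"""

import argparse
from pathlib import Path

from relaxcider import GroundTruthRegistry, decompose_study, generate_study_bundle
from relaxcider.io import read_nmrd_csv, write_json_report
from relaxcider.pipeline import _plot_profiles
from relaxcider.synthetic import DEFAULT_SEED


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    csv = args.out / "nmrd_profiles.csv"
    if csv.exists():
        profiles = {p.sample_id: p for p in read_nmrd_csv(csv)}
    else:
        profiles = generate_study_bundle(seed=args.seed).profiles

    registry = GroundTruthRegistry()
    res = decompose_study(profiles, registry_seeds=registry)
    write_json_report(res.to_dict(), args.out / "decomposition.json")
    _plot_profiles(profiles, res, args.out / "nmrd_decomposition.png")

    print("fitted mechanism parameters (ground truth in brackets):")
    print(f"  background      {res.background:.5f} s^-1  [{registry.background}]")
    print(f"  intraDD (B-A)   {res.intra_dd_delta:.5f} s^-1  [{registry.intra_dd_delta}]")
    print(f"  interDD (E-D)   {res.inter_dd_delta:.5f} s^-1  [{registry.inter_dd_delta}]")
    o2 = res.pre_o2.params
    print(f"  PRE:O2 (D-B)    {o2.amplitude_zero_field:.5f} s^-1, "
          f"tau_c {o2.tau_c * 1e12:.1f} ps  "
          f"[{registry.pre_o2.amplitude_zero_field:.5f}, 6.1 ps]")
    print(f"  PRE:M+ H2O      {res.pre_metal_h2o.params.amplitude_zero_field:.5f} s^-1  [0.0133]")
    print(f"  PRE:M+ D2O      {res.pre_metal_d2o.params.amplitude_zero_field:.5f} s^-1  [0.0113]")
    print(f"  CSA             d_sigma {res.csa.delta_sigma:.1f} +/- "
          f"{res.csa.delta_sigma_sd:.1f} ppm  [136.5]")
    rad = res.radical.params
    print(f"  radical (#G)    {rad.amplitude_zero_field:.5f} s^-1, "
          f"tau_c {rad.tau_c * 1e12:.0f} ps  [placeholder 0.002, 100 ps]")
    print(f"assembled model: rms relative residual {res.rms_relative_residual:.3f} "
          f"over {sum(len(r) for r in res.residuals.values())} points")
    print(f"report -> {args.out / 'decomposition.json'}")


if __name__ == "__main__":
    main()
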