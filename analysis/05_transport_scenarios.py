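#!/usr/bin/env python
"""Polarization retention during transfer for optimized vs standard samples.

Integrates exp(-int dt/T1(B(t))) over transfer scenarios using the additive
model: a constant low-field hold (the short-transfer shorthand, 19.5 s at
1 mT) and a synthetic 60 s ramp trajectory (1 mT hold -> 1 T -> 9.4 T).
Compares the standard dDNP sample #G against the optimized #C and reports
the SNR gain from composition optimization.
"""

import argparse
from pathlib import Path

from relaxcider import (
    GroundTruthRegistry,
    NINE_SAMPLES,
    RelaxationMap,
    constant_field_profile,
    example_ramp_profile,
    retained_polarization,
    snr_gain,
)
from relaxcider.io import write_json_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--duration", type=float, default=19.5,
                    help="constant-field hold duration (s)")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    registry = GroundTruthRegistry()
    maps = {sid: RelaxationMap(composition=NINE_SAMPLES[sid], registry=registry)
            for sid in ("G", "C")}

    report = {}
    hold = constant_field_profile(1e-3, args.duration)
    ramp = example_ramp_profile(60.0)
    for name, profile, duration in (
        (f"hold_1mT_{args.duration:g}s", hold, args.duration),
        ("ramp_60s", ramp, 60.0),
    ):
        rets = {sid: retained_polarization(m, profile, duration)
                for sid, m in maps.items()}
        gain = snr_gain(rets["C"], rets["G"])
        report[name] = {**{f"retained_{s}": r for s, r in rets.items()},
                        "snr_gain_C_vs_G": gain}
        print(f"{name}: #G retains {100 * rets['G']:.1f}%, "
              f"#C retains {100 * rets['C']:.1f}% -> SNR gain {gain:.2f}x")

    # closed-form anchor: at the standard sample's measured low-field T1 of
    # 46.6 s, a 19.5 s transfer retains exp(-19.5/46.6) ~ 66%
    report["closed_form_46p6s"] = retained_polarization(46.6, duration=19.5)
    print(f"closed form (T1=46.6 s, 19.5 s): "
          f"{100 * report['closed_form_46p6s']:.1f}% retained")

    write_json_report(report, args.out / "transport_scenarios.json")
    print(f"report -> {args.out / 'transport_scenarios.json'}")


if __name__ == "__main__":
    main()
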