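#!/usr/bin/env python
"""Flip-angle-corrected T1 and polarization of hyperpolarized decays.

Emulates the benchtop (1 T) measurements of hyperpolarized pyruvate in three
dissolution media — the filtered and unfiltered optimized D2O media and the
standard H2O medium, with lifetimes 162.1, 153.8 and 77.1 s — sampled every
5 s with 10 deg pulses, then recovers the true T1 by removing the RF
consumption rate -ln(cos a)/TR.  Also quantifies liquid-state polarization
from a hyperpolarized/thermal signal pair.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from relaxcider import (
    fit_hyperpolarized_decay,
    generate_decay_series,
    polarization_from_reference,
)
from relaxcider.synthetic import DEFAULT_SEED

MEDIA = {"D2O_filtered": 162.1, "D2O": 153.8, "H2O": 77.1}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    rows = []
    print("flip-angle-corrected T1 (a=10 deg, TR=5 s, 1% noise):")
    for medium, t1_true in MEDIA.items():
        series = generate_decay_series(
            t1_true, "hyperpolarized", flip_angle=10.0, repetition_time=5.0,
            n_points=36, noise_rel=0.01, seed=int(rng.integers(0, 2**31 - 1)),
        )
        fit = fit_hyperpolarized_decay(series)
        rows.append({"medium": medium, "T1_true_s": t1_true, "T1_fit_s": fit.T1,
                     "T1_sd_s": fit.T1_sd, "apparent_T1_s": fit.apparent_T1,
                     "rf_rate_s-1": fit.rf_rate})
        print(f"  {medium:13s} true {t1_true:6.1f} s -> fitted "
              f"{fit.T1:6.1f} +/- {fit.T1_sd:4.1f} s "
              f"(apparent {fit.apparent_T1:5.1f} s)")
    pd.DataFrame(rows).to_csv(args.out / "hyperpolarized_decay.csv",
                              index=False, float_format="%.6g")

    # polarization quantification: an enhancement of 4.06e5 over the thermal
    # 13C signal at 1 T / 293 K corresponds to ~35.6% polarization
    pol = polarization_from_reference(4.06e5, 1.0, 1)
    print(f"enhancement 4.06e5 at 1 T, 293 K -> polarization {pol:.1f}%")
    print(f"table -> {args.out / 'hyperpolarized_decay.csv'}")


if __name__ == "__main__":
    main()
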