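#!/usr/bin/env python
"""Recover the mycotoxin pKa values from synthetic ionization curves.

Generates two-state intensity-vs-pH series at the two reference acidity
constants (6.2 for beta-zearalenol; 7.8 shared by zearalenone and
alpha-zearalenol), fits them noise-free and across 200 noisy replicates,
and writes results/pka_recovery.csv.  Also illustrates the apparent-pKa
shift induced by a host that binds only the neutral guest.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hostguest_titrate import apparent_pka_shift, fit_pka, generate_ph_series


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/pka_recovery.csv"))
    args = parser.parse_args()

    rows = []
    for label, truth in (("beta-ZOL", 6.2), ("ZEN/alpha-ZOL", 7.8)):
        clean = fit_pka(generate_ph_series(truth, 100.0, 300.0))
        reps = [
            fit_pka(generate_ph_series(truth, 100.0, 300.0, noise_sd_rel=0.01,
                                       seed=args.seed * 1000 + r)).pka
            for r in range(200)
        ]
        rows.append({
            "compound": label, "true_pka": truth,
            "noise_free_fit": round(clean.pka, 6),
            "replicate_mean": round(float(np.mean(reps)), 4),
            "replicate_sd": round(float(np.std(reps)), 4),
        })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(df.to_string(index=False))

    shift = apparent_pka_shift(6.2, 10**3.88, 2.0e-3)
    print(f"\napparent pKa of beta-ZOL at 2 mM free DIMEB "
          f"(neutral-guest-only binding): {shift:.2f} (vs intrinsic 6.2)")


if __name__ == "__main__":
    main()
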