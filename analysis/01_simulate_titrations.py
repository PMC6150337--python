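#!/usr/bin/env python
"""Generate the synthetic titration library.

For every guest-cyclodextrin pair with a reference binding constant, one
noisy fluorescence titration is generated at the study conditions (2 uM
guest on the 0-2.0 mM 11-point host grid, 0.5% relative noise) through the
exact mass-action speciation solver, and written as CSV under
results/titrations/.  These files are the inputs for 02_fit_binding.py.
"""

import argparse
from pathlib import Path

from hostguest_titrate import BindingModel, TitrationSimSpec, generate_titration_speciation
from hostguest_titrate.io import write_titration_csv
from hostguest_titrate.reference_data import load_global_log_k

EMISSIVITIES = {"free": 5e7, (1, 1): 3.5e8}  # a.u. per mol/dm^3 of guest


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/titrations"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = load_global_log_k()
    for i, row in table.iterrows():
        spec = TitrationSimSpec(
            model=BindingModel.one_to_one(row.log_beta),
            noise_sd_rel=0.005,
            seed=args.seed * 1000 + i,
        )
        series = generate_titration_speciation(spec, EMISSIVITIES)
        path = args.outdir / f"{row.guest}_{row.host}.csv"
        write_titration_csv(series, path)
        print(f"wrote {path}  (true log beta = {row.log_beta:.2f})")
    print(f"\n{len(table)} titrations under {args.outdir}")


if __name__ == "__main__":
    main()
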