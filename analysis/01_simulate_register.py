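"""Generate the synthetic primary-care visit register.

The register stands in for the non-public national extract: ~8 500
patients, ~1 566 professionals across 7 municipalities of very unequal
size, ~150 000 visits in one calendar year, with known ground truth.
Writes register.csv and ground_truth.json into the output directory.
"""

import argparse
from pathlib import Path

from psnet.registry_io import write_visits
from psnet.synthetic_data import SyntheticConfig, simulate_register


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=str, default="scratch/run")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg = SyntheticConfig(seed=args.seed)
    table, truth = simulate_register(cfg)
    write_visits(table, out / "register.csv")
    truth.to_json(out / "ground_truth.json")
    print(
        f"simulated {len(table)} visits for {table.n_patients} patients and "
        f"{table.n_professionals} professionals (seed {args.seed})"
    )
    print(f"filter-exercising rows injected: {truth.injected}")
    print(f"wrote {out / 'register.csv'} and {out / 'ground_truth.json'}")


if __name__ == "__main__":
    main()
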