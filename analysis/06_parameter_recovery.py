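"""Parameter-recovery study for the dyadic ERGM estimator.

Samples networks exactly from a known dyad-independent ERGM and refits
them, reporting per-term bias, RMSE and 95%-CI coverage.  With 200
replicates at N=300 nodes the estimator should be essentially unbiased
with near-nominal coverage.
"""

import argparse
from pathlib import Path

import pandas as pd

from psnet.ergm import edges, nodefactor, nodematch
from psnet.synthetic_data import recovery_experiment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=200)
    ap.add_argument("--results-dir", type=str, default="results")
    args = ap.parse_args()
    results = Path(args.results_dir)
    results.mkdir(parents=True, exist_ok=True)

    attrs = pd.DataFrame(
        {"occupation_group": ["physician"] * 150 + ["nurse"] * 150},
        index=[f"h{i:03d}" for i in range(300)],
    )
    report = recovery_experiment(
        attrs,
        theta_true=[-2.0, -0.3, 0.5],
        terms=[edges(), nodefactor("occupation_group", "physician"),
               nodematch("occupation_group")],
        replicates=args.replicates,
        seed=args.seed,
    )
    report.round(4).to_csv(results / "recovery.csv")
    print(report.round(4).to_string())
    print(
        f"\nmax |bias| {report['bias'].abs().max():.4f}; coverage range "
        f"[{report['coverage'].min():.3f}, {report['coverage'].max():.3f}]"
    )


if __name__ == "__main__":
    main()
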