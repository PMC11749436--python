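"""Apply the cohort-selection cascade to the register.

Restricts to the study year and adult patients, selects patients with at
least one mental-health/substance-use visit, drops home-care and
uninformative-service visits, visits without an identifiable
professional, and patients whose visits cannot carry patient-sharing
information.  Prints the per-stage audit table and assigns each
professional a unique municipality, occupation group and service type by
the majority of their visits.
"""

import argparse
from pathlib import Path

from psnet.cohort_filter import apply_cohort_filters, assign_primary_attributes
from psnet.registry_io import read_visits, write_node_attrs, write_visits


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=str, default="scratch/run")
    ap.add_argument("--results-dir", type=str, default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)
    results = Path(args.results_dir)
    results.mkdir(parents=True, exist_ok=True)

    table = read_visits(out / "register.csv")
    filtered, report = apply_cohort_filters(table)
    attrs = assign_primary_attributes(filtered)

    write_visits(filtered, out / "filtered.csv")
    write_node_attrs(attrs, out / "attributes.csv")
    report.to_csv(results / "filter_report.csv")
    print(report.to_text())
    print(
        f"\nretained {len(filtered)} visits, {filtered.n_patients} patients, "
        f"{filtered.n_professionals} professionals"
    )
    print(f"attribute mix:\n{attrs.apply(lambda c: c.value_counts()).fillna(0)}")


if __name__ == "__main__":
    main()
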