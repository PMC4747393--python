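#!/usr/bin/env python
"""Classify the packaged study cohort into poor/neutral phenotypes.

Writes results/cohort/phenotypes.tsv and results/cohort/summary.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lynchmod.cohort import classify_phenotype, cohort_summary, load_study_cohort

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--age-cutoff", type=int, default=50)
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "cohort")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    subjects = load_study_cohort()
    rows = []
    for s in subjects:
        label = classify_phenotype(s, args.age_cutoff)
        rows.append(
            {
                "subject_id": s.subject_id,
                "family_id": s.family_id or "",
                "age_ec": s.age_ec_diagnosis,
                "n_other_tumors": len(s.non_ec_tumors),
                "mmr_gene": s.familial_mutation.gene,
                "ngs_ok": s.ngs_passed_qc,
                "phenotype": label.label,
                "reasons": ";".join(label.reasons),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(args.out_dir / "phenotypes.tsv", sep="\t", index=False)

    summary = cohort_summary(subjects)
    (args.out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    print(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
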