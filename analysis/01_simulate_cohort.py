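#!/usr/bin/env python
"""Simulate a synthetic carrier cohort and write its fixture files.

Writes results/synthetic_cohort/<seed>/ with the full pipeline input set
(clinical table, VCF, MAF table, panel BED + metadata, prior annotations,
toy transcripts GFF3 + FASTA) plus the generator's truth.json.
"""

import argparse
from pathlib import Path

from lynchmod.synthetic import SimulationConfig, simulate_cohort, write_fixture

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--n-subjects", type=int, default=35)
    parser.add_argument("--odds-ratio", type=float, default=14.7)
    parser.add_argument(
        "--out-dir", type=Path, default=ROOT / "results" / "synthetic_cohort"
    )
    args = parser.parse_args()

    cohort = simulate_cohort(
        SimulationConfig(
            seed=args.seed, n_subjects=args.n_subjects, odds_ratio=args.odds_ratio
        )
    )
    out = args.out_dir / str(args.seed)
    paths = write_fixture(cohort, out)
    n_poor = sum(1 for t in cohort.truth.values() if t["phenotype"] == "poor")
    print(f"wrote {len(paths)} fixture files to {out}")
    print(
        f"subjects: {len(cohort.subjects)}  variants: {len(cohort.records)}  "
        f"poor: {n_poor}"
    )


if __name__ == "__main__":
    main()
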