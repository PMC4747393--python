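#!/usr/bin/env python
"""Association statistics on the published burden-phenotype distribution.

Writes results/association/published_tests.json: the 6x2 Pearson chi-square,
the k=2 dichotomized table and its two-sided Fisher exact p, plus the same
dichotomy at every other cut point for sensitivity.
"""

import argparse
import json
import warnings
from pathlib import Path

from lynchmod.association import (
    dichotomize,
    fisher_exact_2x2,
    load_published_burden_distribution,
    pearson_chi_square,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--out-dir", type=Path, default=ROOT / "results" / "association"
    )
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    table = load_published_burden_distribution()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chi = pearson_chi_square(table)

    payload = {
        "burden_table": {
            "rows": table.row_labels,
            "cols": table.col_labels,
            "counts": table.counts,
        },
        "chi_square": {
            "statistic": chi.statistic,
            "df": chi.df,
            "p_value": chi.p_value,
        },
        "dichotomies": {},
    }
    for k in range(1, len(table.row_labels)):
        two = dichotomize(table, k)
        payload["dichotomies"][f"k={k}"] = {
            "rows": two.row_labels,
            "counts": two.counts,
            "fisher_p": fisher_exact_2x2(two).p_value,
        }

    out = args.out_dir / "published_tests.json"
    out.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    print(json.dumps(payload, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
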