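#!/usr/bin/env python
"""Exposure-time experiment: Kruskal-Wallis with Dunn's post hoc.

Compares each exposure arm (2/6/12/24 h with females) against the naive
control on the table from 01; number signs mark arms whose Dunn-adjusted p
falls below 0.05.  The expected pattern is an effect only at >= 12 h.
Writes results/exposure_time_dunn.csv.
"""

from pathlib import Path

import pandas as pd

from mateguard.pipeline import read_table
from mateguard.stats import compare_experiment

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20230522


def main() -> None:
    table = read_table(ROOT / "data" / "md_exposure_time.csv", "md")
    comparison, estimation, multi = compare_experiment(
        table,
        group_by=("genotype",),
        reference="CS_naive",
        seed=SEED,
    )
    print(f"Kruskal-Wallis H = {multi.kw_H:.2f}, p = {multi.kw_p:.2e}")
    rows = []
    for comp in multi.comparisons:
        arm = comp.pair[1]
        mark = "#" if comp.hash_mark else " "
        print(f"  {arm:>8}: z = {comp.z:6.2f}, adj p = {comp.p_adjusted:.4f} {mark}")
        rows.append(
            {
                "arm": arm,
                "rank_mean_difference": comp.rank_mean_difference,
                "z": comp.z,
                "p_adjusted": comp.p_adjusted,
                "hash_mark": comp.hash_mark,
            }
        )
    out = ROOT / "exposure_time_dunn.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
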