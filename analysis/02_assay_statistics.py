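#!/usr/bin/env python
"""Per-strain naive-vs-experienced comparisons with estimation statistics.

For each strain table from 01: apply the one-hour inclusion filter, check
normality, run the Student's t test with star annotation, the percent
reduction and a 5000-resample bootstrap CI of the mean difference.  Writes
results/assay_comparisons.csv.
"""

from pathlib import Path

import pandas as pd

from mateguard.pipeline import read_table
from mateguard.stats import compare_experiment

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20230522


def main() -> None:
    rows = []
    for path in sorted((ROOT / "data").glob("md_*.csv")):
        if "exposure" in path.name:
            continue
        strain = path.stem.removeprefix("md_")
        table = read_table(path, "md")
        comparison, estimation = compare_experiment(table, reference="naive", seed=SEED)
        rows.append(
            {
                "strain": strain,
                "n_naive": comparison.n[0],
                "n_experienced": comparison.n[1],
                "mean_naive_s": comparison.means[0],
                "mean_experienced_s": comparison.means[1],
                "percent_reduction": comparison.percent_reduction,
                "t": comparison.t_statistic,
                "df": comparison.degrees_of_freedom,
                "p": comparison.p_value,
                "stars": comparison.stars,
                "normality_p_naive": comparison.normality_p[0],
                "normality_p_experienced": comparison.normality_p[1],
                "mean_diff_s": estimation.mean_difference,
                "ci_low_s": estimation.ci_low,
                "ci_high_s": estimation.ci_high,
            }
        )
        print(
            f"{strain}: reduction {comparison.percent_reduction:5.1f}% {comparison.stars}"
            f"  diff {estimation.mean_difference:7.1f} s"
            f" [{estimation.ci_low:.1f}, {estimation.ci_high:.1f}]"
        )
    out = ROOT / "assay_comparisons.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
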