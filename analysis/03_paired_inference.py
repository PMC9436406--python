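"""Paired nonparametric inference on the cohort matrices.

For each readout: exact Wilcoxon signed-rank test of every treatment against
the untreated 72 h control with Benjamini-Hochberg correction across the
four comparisons, and a Friedman test with Kendall's W across all
conditions.  Results go to results/inference/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from slicequant.annotation_io import write_readout_table
from slicequant.stats import compare_conditions, friedman_test, paired_results_frame


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--readouts", type=Path, default=Path("results/readouts"))
    parser.add_argument("--out", type=Path, default=Path("results/inference"))
    parser.add_argument("--control", default="control_72h")
    args = parser.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    frames = []
    friedman = {}
    for readout in ("viability_pct", "outgrowth_pct", "tvi"):
        matrix = pd.read_csv(args.readouts / f"matrix_{readout}.csv", index_col=0)
        results = compare_conditions(matrix, args.control)
        frame = paired_results_frame(results)
        frame.insert(0, "readout", readout)
        frames.append(frame)
        fr = friedman_test(matrix)
        friedman[readout] = {
            "n_blocks": fr.n_blocks, "chi2": fr.chi2, "df": fr.df,
            "p_value": fr.p_value, "kendalls_w": fr.kendalls_w,
        }
        sig = frame[frame["p_adjusted"] <= 0.05]["comparison"].tolist()
        print(
            f"{readout}: significant vs control (BH p<=0.05): {sig or 'none'}; "
            f"Friedman p = {fr.p_value:.2g}, Kendall's W = {fr.kendalls_w:.3f}"
        )

    write_readout_table(pd.concat(frames, ignore_index=True), args.out / "paired_tests.csv")
    (args.out / "friedman.json").write_text(json.dumps(friedman, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
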