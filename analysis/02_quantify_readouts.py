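"""Quantify drug response per slice and per culture x condition.

Reads the annotation table from results/cohort/, computes the three readouts
(viability %, outgrowth length %, tumor viability index), averages duplicate
slices, assembles cohort matrices with per-condition medians, and grades
damage on the Evans scale.  Artifacts go to results/readouts/.
"""

import argparse
from pathlib import Path

from slicequant.annotation_io import read_annotation_table, write_readout_table
from slicequant.readouts import (
    average_duplicates,
    cohort_matrix,
    compute_slice_readouts,
    evans_grade,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/readouts"))
    args = parser.parse_args()

    table = read_annotation_table(args.cohort / "annotations.csv")
    slices = compute_slice_readouts(table)
    summaries = average_duplicates(slices)
    args.out.mkdir(parents=True, exist_ok=True)
    write_readout_table(slices, args.out / "slice_readouts.csv")
    write_readout_table(summaries, args.out / "condition_summaries.csv")

    cond_order = list(dict.fromkeys(table["condition"]))
    for readout in ("viability_pct", "outgrowth_pct", "tvi"):
        matrix, medians, pooled = cohort_matrix(summaries, readout, condition_order=cond_order)
        write_readout_table(matrix.reset_index(), args.out / f"matrix_{readout}.csv")
        printable = ", ".join(f"{c}={v:.1f}" for c, v in medians.items())
        print(f"{readout}: medians {printable}; pooled selenite {pooled:.1f}")

    summaries["evans_grade"] = [
        evans_grade(min(100.0, max(0.0, d))) for d in summaries["damaged_pct"]
    ]
    write_readout_table(
        summaries[["culture_id", "condition", "damaged_pct", "evans_grade"]],
        args.out / "evans_grades.csv",
    )
    major = summaries[summaries["evans_grade"].isin(["III", "IV"])]
    for cond in cond_order:
        n = int((major["condition"] == cond).sum())
        print(f"Evans III-IV (>90% damaged) in {cond}: {n} cultures")


if __name__ == "__main__":
    main()
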