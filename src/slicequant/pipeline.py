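"""End-to-end orchestration: simulate/ingest → readouts → stats → DE filter → report.

Each stage writes its artifact under the output directory and failures abort
with a stage-named error, so a broken run is diagnosable from the last file
written.  A manifest (config dump, seed, version) makes a bundle exactly
reproducible: same config + seed gives byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import RunConfig
from .annotation_io import validate_annotation_table, read_annotation_table, write_readout_table
from .de_filter import initial_significance, strict_filter, summarize_de, read_de_table
from .readouts import (
    MorphologyGrouping,
    average_duplicates,
    cohort_matrix,
    compute_slice_readouts,
    evans_grade,
)
from .stats import compare_conditions, friedman_test, paired_results_frame
from .synth import generate_cohort, generate_de_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    config: RunConfig
    annotations: pd.DataFrame
    slice_readouts: pd.DataFrame
    condition_summaries: pd.DataFrame
    matrices: dict = field(default_factory=dict)  # readout -> culture x condition
    medians: dict = field(default_factory=dict)  # readout -> {condition: median}
    pooled_medians: dict = field(default_factory=dict)  # readout -> pooled selenite
    evans: Optional[pd.DataFrame] = None
    paired_tests: Optional[pd.DataFrame] = None
    friedman: dict = field(default_factory=dict)  # readout -> FriedmanResult fields
    de_summary: Optional[dict] = None
    manifest: dict = field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    # out_dir does not affect bundle content, so it is excluded from the hash
    payload = config.model_dump(mode="json")
    payload.pop("out_dir", None)
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages and write the report bundle under ``config.out_dir``."""
    from . import __version__

    # Config-level checks fail before any compute.
    if config.synthetic is not None:
        if config.control_condition not in config.synthetic.condition_labels:
            raise PipelineError(
                "config",
                f"control condition {config.control_condition!r} not among "
                f"configured conditions {config.synthetic.condition_labels}",
            )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: input -----------------------------------------------------
    try:
        if config.synthetic is not None:
            synth_cfg = config.synthetic.model_copy(update={"seed": config.seed})
            annotations, truth = generate_cohort(synth_cfg)
            (out / "ground_truth.json").write_text(
                json.dumps(truth.to_json_dict(), indent=2, sort_keys=True)
            )
        else:
            annotations = read_annotation_table(config.annotation_table)
        annotations = validate_annotation_table(annotations)
        if config.control_condition not in set(annotations["condition"]):
            raise ValueError(
                f"control condition {config.control_condition!r} not present in data"
            )
        write_readout_table(annotations, out / "annotations.csv")
        logger.info("input: %d annotation records", len(annotations))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    # --- stage: readouts --------------------------------------------------
    try:
        grouping = MorphologyGrouping(
            weights={"viable": config.viable_weight, "damaged": config.damaged_weight}
        )
        slices = compute_slice_readouts(annotations, grouping)
        summaries = average_duplicates(slices)
        write_readout_table(slices, out / "slice_readouts.csv")
        write_readout_table(summaries, out / "condition_summaries.csv")
        logger.info("readouts: %d slices -> %d condition summaries", len(slices), len(summaries))

        cond_order = list(dict.fromkeys(annotations["condition"]))
        matrices, medians, pooled = {}, {}, {}
        for readout in ("viability_pct", "outgrowth_pct", "tvi"):
            m, med, pool = cohort_matrix(summaries, readout, condition_order=cond_order)
            matrices[readout] = m
            medians[readout] = {c: float(v) for c, v in med.items()}
            pooled[readout] = pool
            write_readout_table(m.reset_index(), out / f"matrix_{readout}.csv")

        evans = summaries[["culture_id", "condition", "damaged_pct"]].copy()
        evans["evans_grade"] = [
            evans_grade(min(100.0, max(0.0, d)), config.evans_thresholds)
            if pd.notna(d)
            else None
            for d in evans["damaged_pct"]
        ]
        write_readout_table(evans, out / "evans_grades.csv")
    except Exception as exc:
        raise PipelineError("readouts", str(exc)) from exc

    # --- stage: stats -----------------------------------------------------
    try:
        viability_matrix = matrices["viability_pct"]
        if viability_matrix.shape[0] < 2:
            raise ValueError("need at least 2 cultures for paired inference")
        test_frames = []
        friedman: dict = {}
        for readout in config.readouts_to_test:
            matrix = matrices[readout]
            results = compare_conditions(
                matrix, config.control_condition, family=config.bh_family
            )
            frame = paired_results_frame(results)
            frame.insert(0, "readout", readout)
            test_frames.append(frame)
            fr = friedman_test(matrix)
            friedman[readout] = {
                "n_blocks": fr.n_blocks,
                "k_treatments": fr.k_treatments,
                "chi2": fr.chi2,
                "df": fr.df,
                "p_value": fr.p_value,
                "kendalls_w": fr.kendalls_w,
                "n_dropped_blocks": fr.n_dropped_blocks,
            }
        paired = pd.concat(test_frames, ignore_index=True)
        write_readout_table(paired, out / "paired_tests.csv")
        (out / "friedman.json").write_text(json.dumps(friedman, indent=2, sort_keys=True))
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    # --- stage: de-filter -------------------------------------------------
    de_summary = None
    try:
        de_table = None
        if config.de_table is not None:
            de_table = read_de_table(config.de_table)
        elif config.synthetic is not None:
            de_table = generate_de_table(
                n_genes=20000, n_signal=300, seed=config.seed
            )
        if de_table is not None:
            flagged = initial_significance(de_table)
            strict = strict_filter(flagged)
            de_summary = summarize_de(flagged)
            write_readout_table(flagged, out / "de_flagged.csv")
            write_readout_table(strict, out / "de_strict.csv")
            (out / "de_summary.json").write_text(
                json.dumps(de_summary, indent=2, sort_keys=True)
            )
    except Exception as exc:
        raise PipelineError("de_filter", str(exc)) from exc

    # --- stage: report ----------------------------------------------------
    bundle = ReportBundle(
        config=config,
        annotations=annotations,
        slice_readouts=slices,
        condition_summaries=summaries,
        matrices=matrices,
        medians=medians,
        pooled_medians=pooled,
        evans=evans,
        paired_tests=paired,
        friedman=friedman,
        de_summary=de_summary,
        manifest={
            "config": json.loads(config.model_dump_json()),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
        },
    )
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True)
    )
    (out / "report.md").write_text(render_summary(bundle))
    return bundle


def render_summary(bundle: ReportBundle, alpha: float = 0.05) -> str:
    """One-page markdown report: medians, Evans grade counts, test tables."""
    lines = ["# Slice drug-response report", ""]
    lines.append(f"Cultures: {bundle.matrices['viability_pct'].shape[0]}; "
                 f"conditions: {bundle.matrices['viability_pct'].shape[1]}")
    lines.append("")
    lines.append("## Per-condition medians")
    lines.append("")
    lines.append("| readout | " + " | ".join(bundle.matrices["viability_pct"].columns) + " | pooled selenite |")
    lines.append("|" + "---|" * (len(bundle.matrices["viability_pct"].columns) + 2))
    for readout, med in bundle.medians.items():
        cells = [f"{med.get(c, float('nan')):.1f}" for c in bundle.matrices[readout].columns]
        pooled = bundle.pooled_medians[readout]
        lines.append(f"| {readout} | " + " | ".join(cells) + f" | {pooled:.1f} |")
    lines.append("")

    if bundle.evans is not None and len(bundle.evans):
        lines.append("## Major responses (>90% damaged tumor, Evans III-IV)")
        lines.append("")
        counts = (
            bundle.evans[bundle.evans["evans_grade"].isin(["III", "IV"])]
            .groupby("condition")
            .size()
        )
        for cond in bundle.matrices["viability_pct"].columns:
            lines.append(f"- {cond}: {int(counts.get(cond, 0))} cultures")
        lines.append("")

    if bundle.paired_tests is not None:
        lines.append(f"## Paired Wilcoxon signed-rank vs control (BH-adjusted, alpha={alpha})")
        lines.append("")
        lines.append("| readout | comparison | n | W | p | p_adj | sig |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, r in bundle.paired_tests.iterrows():
            sig = "*" if (r["p_adjusted"] is not None and r["p_adjusted"] <= alpha) else ""
            lines.append(
                f"| {r['readout']} | {r['comparison']} | {r['n_effective']} "
                f"| {r['statistic_w']:.1f} | {r['p_two_sided']:.4f} "
                f"| {r['p_adjusted']:.4f} | {sig} |"
            )
        lines.append("")

    if bundle.friedman:
        lines.append("## Friedman test across conditions")
        lines.append("")
        for readout, fr in bundle.friedman.items():
            lines.append(
                f"- {readout}: chi2({fr['df']}) = {fr['chi2']:.2f}, "
                f"p = {fr['p_value']:.2g}, Kendall's W = {fr['kendalls_w']:.3f}"
            )
        lines.append("")

    lines.append("## Differential expression")
    lines.append("")
    if bundle.de_summary is None:
        lines.append("not run")
    else:
        s = bundle.de_summary
        lines.append(
            f"{s['n_up']} genes (out of {s['n_total']}, {s['pct_up']:.1f}%) "
            f"overexpressed and {s['n_down']} ({s['pct_down']:.1f}%) underexpressed; "
            f"{s['n_strict']} genes pass the strict filter "
            f"(p <= 1e-4, >= 350 reads)."
        )
    lines.append("")
    return "\n".join(lines)
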