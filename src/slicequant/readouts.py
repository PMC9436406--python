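"""Per-slice drug-response readouts and cohort summaries.

Three readouts quantify treatment-induced tumor cell damage:

* **viability %** — viable / (viable + damaged) × 100, over morphologically
  classified cancer-cell outgrowth lengths (outgrowth-mode cultures) or over
  annotated tumor areas within the slice (area-mode cultures);
* **outgrowth %** — total cancer-cell outgrowth length as a percentage of
  the slice perimeter;
* **tumor viability index (TVI)** — Σ over {viable, damaged} of
  (% outgrowth length × weight), weights 3 and 1, range 0–300.

Slice readouts are averaged over duplicate slices per culture × condition,
assembled into culture × condition matrices with per-condition medians, and
damage is mapped to Evans tumor-regression grades.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-6


class DataError(ValueError):
    """Slice data violate a readout precondition (e.g. missing perimeter)."""


@dataclass(frozen=True)
class MorphologyGrouping:
    """Maps outgrowth morphology classes to viable/damaged groups and weights.

    Flat, cubic, cylindrical and clear cell outgrowth counts as viable;
    swollen and necro-apoptotic outgrowth as severely damaged.  Weights
    (default 3 for viable, 1 for damaged) feed the tumor viability index.
    """

    class_to_group: dict = field(
        default_factory=lambda: {
            "flat": "viable",
            "cubic": "viable",
            "cylindrical": "viable",
            "clear": "viable",
            "swollen": "damaged",
            "necro_apoptotic": "damaged",
        }
    )
    weights: dict = field(default_factory=lambda: {"viable": 3.0, "damaged": 1.0})

    def __post_init__(self):
        if set(self.class_to_group.values()) - set(self.weights):
            raise ValueError("every group needs a weight")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be strictly positive")


def classify_group(
    annotation_class: str, grouping: MorphologyGrouping | None = None
) -> str:
    """Return 'viable' or 'damaged' for an outgrowth morphology class."""
    grouping = grouping or MorphologyGrouping()
    try:
        return grouping.class_to_group[annotation_class]
    except KeyError:
        raise ValueError(
            f"{annotation_class!r} is not an outgrowth morphology class"
        ) from None


def tumor_viability_index(
    viable_len_pct: float,
    damaged_len_pct: float,
    viable_weight: float = 3.0,
    damaged_weight: float = 1.0,
) -> float:
    """Tumor viability index: weighted sum of outgrowth-length percentages.

    ``TVI = viable_weight * viable_len_pct + damaged_weight * damaged_len_pct``
    (defaults 3 and 1).  Inputs are percentages of the slice perimeter; their
    sum may not exceed 100 (up to numerical tolerance).
    """
    if viable_len_pct < 0 or damaged_len_pct < 0:
        raise ValueError("outgrowth-length percentages must be non-negative")
    if viable_len_pct + damaged_len_pct > 100.0 + _SUM_TOL:
        raise ValueError("viable + damaged outgrowth cannot exceed the perimeter")
    return viable_weight * viable_len_pct + damaged_weight * damaged_len_pct


@dataclass
class SliceReadout:
    """Derived quantities for one slice."""

    culture_id: str
    condition: str
    slice_id: str
    mode: str  # 'outgrowth' or 'area'
    class_pct: dict  # per-class % of perimeter (outgrowth mode)
    viable_len_pct: float
    damaged_len_pct: float
    outgrowth_pct: float
    viability_pct: float  # NaN when no tumor measured
    tvi: float  # NaN in area mode

    def as_row(self) -> dict:
        row = {
            "culture_id": self.culture_id,
            "condition": self.condition,
            "slice_id": self.slice_id,
            "mode": self.mode,
            "viable_len_pct": self.viable_len_pct,
            "damaged_len_pct": self.damaged_len_pct,
            "outgrowth_pct": self.outgrowth_pct,
            "viability_pct": self.viability_pct,
            "tvi": self.tvi,
        }
        row.update({f"pct_{cls}": v for cls, v in self.class_pct.items()})
        return row


def slice_readouts(
    records: pd.DataFrame, grouping: MorphologyGrouping | None = None
) -> SliceReadout:
    """Compute the readouts for the annotation records of a single slice.

    Outgrowth mode (exactly one positive perimeter record expected): per-class
    percentage of perimeter, viable/damaged group sums, outgrowth %, viability
    % of outgrowth, and TVI.  Area mode (tumor viable/damaged area records):
    viability % of annotated tumor area; outgrowth readouts and TVI are
    undefined (NaN).  Multiple records of one class on one slice (disjoint
    annotations) are summed.
    """
    grouping = grouping or MorphologyGrouping()
    culture = str(records["culture_id"].iloc[0])
    condition = str(records["condition"].iloc[0])
    slice_id = str(records["slice_id"].iloc[0])

    by_class = records.groupby("annotation_class")["value"].sum()
    area_mode = ("tumor_viable_area" in by_class) or ("tumor_damaged_area" in by_class)

    if area_mode:
        viable_a = float(by_class.get("tumor_viable_area", 0.0))
        damaged_a = float(by_class.get("tumor_damaged_area", 0.0))
        total = viable_a + damaged_a
        if total <= 0:
            raise DataError(f"slice {slice_id}: no positive tumor area measured")
        return SliceReadout(
            culture, condition, slice_id, "area", {},
            viable_len_pct=math.nan, damaged_len_pct=math.nan,
            outgrowth_pct=math.nan,
            viability_pct=100.0 * viable_a / total,
            tvi=math.nan,
        )

    perim_rows = records[records["measure_kind"] == "perimeter"]
    if len(perim_rows) == 0 or perim_rows["value"].sum() <= 0:
        raise DataError(f"slice {slice_id}: missing or zero perimeter record")
    perimeter = float(perim_rows["value"].sum())

    class_pct: dict[str, float] = {}
    group_pct = {"viable": 0.0, "damaged": 0.0}
    for cls, total_len in by_class.items():
        if cls == "perimeter":
            continue
        pct = 100.0 * float(total_len) / perimeter
        class_pct[cls] = pct
        group_pct[classify_group(cls, grouping)] += pct

    viable_pct = group_pct["viable"]
    damaged_pct = group_pct["damaged"]
    outgrowth_pct = viable_pct + damaged_pct
    if outgrowth_pct > 0:
        viability = 100.0 * viable_pct / outgrowth_pct
    else:
        logger.warning("slice %s: no outgrowth measured; viability undefined", slice_id)
        viability = math.nan
    tvi = (
        grouping.weights["viable"] * viable_pct
        + grouping.weights["damaged"] * damaged_pct
    )
    return SliceReadout(
        culture, condition, slice_id, "outgrowth", class_pct,
        viable_len_pct=viable_pct, damaged_len_pct=damaged_pct,
        outgrowth_pct=outgrowth_pct, viability_pct=viability, tvi=tvi,
    )


def compute_slice_readouts(
    table: pd.DataFrame, grouping: MorphologyGrouping | None = None
) -> pd.DataFrame:
    """Per-slice readouts for a whole validated annotation table."""
    rows = [
        slice_readouts(grp, grouping).as_row()
        for _, grp in table.groupby(["culture_id", "condition", "slice_id"], sort=True)
    ]
    return pd.DataFrame(rows)


#: Readouts carried into condition summaries and matrices.
SUMMARY_READOUTS = ("viability_pct", "outgrowth_pct", "tvi")


def average_duplicates(slice_table: pd.DataFrame) -> pd.DataFrame:
    """Average readouts over duplicate slices per culture × condition.

    Missing values (e.g. viability on a zero-outgrowth slice, TVI on
    area-mode slices) are ignored in the mean; the number of contributing
    slices is recorded.  Adds ``damaged_pct`` = 100 − viability % for Evans
    grading.
    """
    if slice_table.empty:
        logger.warning("no slice readouts to average")
        return pd.DataFrame(
            columns=["culture_id", "condition", *SUMMARY_READOUTS, "damaged_pct", "n_slices"]
        )
    grouped = slice_table.groupby(["culture_id", "condition"], sort=True)
    out = grouped[list(SUMMARY_READOUTS)].mean()
    out["n_slices"] = grouped.size()
    out["damaged_pct"] = 100.0 - out["viability_pct"]
    return out.reset_index()


def cohort_matrix(
    summaries: pd.DataFrame,
    readout: str,
    selenite_conditions: tuple[str, ...] = ("se5", "se15", "se30"),
    condition_order: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Assemble a culture × condition matrix for one readout.

    Returns the matrix (missing cells allowed), the per-condition median over
    cultures, and the pooled median over all selenite conditions combined
    (pooling the duplicate-averaged condition summaries).
    """
    if readout not in SUMMARY_READOUTS:
        raise ValueError(f"unknown readout {readout!r}; expected one of {SUMMARY_READOUTS}")
    matrix = summaries.pivot(index="culture_id", columns="condition", values=readout)
    if condition_order:
        matrix = matrix.reindex(columns=[c for c in condition_order if c in matrix.columns])
    medians = matrix.median(axis=0, skipna=True)
    pooled_cols = [c for c in matrix.columns if c in selenite_conditions]
    pooled = float(np.nanmedian(matrix[pooled_cols].to_numpy())) if pooled_cols else math.nan
    return matrix, medians, pooled


def evans_grade(
    damaged_pct: float, thresholds: tuple[float, float, float] = (10.0, 50.0, 90.0)
) -> str:
    """Evans tumor-regression grade from the percentage of damaged tumor cells.

    <10% → I; 10–50% → IIa; >50–90% → IIb; >90% → III; 100% → IV.  Only the
    >90% ⇒ III–IV anchor is study-defined; intermediate bands follow the
    Evans scheme and are configurable.
    """
    if not (0.0 <= damaged_pct <= 100.0):
        raise ValueError(f"damaged_pct must be in [0, 100], got {damaged_pct}")
    t1, t2, t3 = thresholds
    if damaged_pct == 100.0:
        return "IV"
    if damaged_pct > t3:
        return "III"
    if damaged_pct > t2:
        return "IIb"
    if damaged_pct >= t1:
        return "IIa"
    return "I"
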