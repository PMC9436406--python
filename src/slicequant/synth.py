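"""Synthetic annotation-measurement cohorts and differential-expression tables.

The generator emulates the statistical structure of an organotypic
tissue-slice drug test: per-patient baseline viable fractions, an Emax/Hill
dose response to sodium selenite, a Bernoulli per-patient gemcitabine
responder flag, duplicate slices with logit-normal noise, six outgrowth
morphology classes whose lengths partition the viable and damaged outgrowth,
and a minority of patients quantified by within-slice tumor area instead of
outgrowth.  Ground truth is returned alongside so parameter-recovery tests
can compare pipeline readouts with the generating expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SyntheticConfig, ConditionSpec

VIABLE_CLASSES = ("flat", "cubic", "cylindrical", "clear")
DAMAGED_CLASSES = ("swollen", "necro_apoptotic")

_LOGIT_EPS = 1e-9


@dataclass
class GroundTruth:
    """Generating expectations for one synthetic cohort.

    Attributes
    ----------
    v0 : dict
        Baseline viable fraction per culture.
    viable_fraction : dict
        Expected viable fraction per (culture, condition).
    outgrowth_fraction : dict
        Expected outgrowth fraction of the perimeter per (culture, condition).
    gem_responder : dict
        Whether each culture responds to the non-selenite arm.
    mode : dict
        Quantification mode per culture: ``outgrowth`` or ``area``.
    """

    v0: dict[str, float] = field(default_factory=dict)
    viable_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    outgrowth_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    gem_responder: dict[str, bool] = field(default_factory=dict)
    mode: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        """JSON-serializable form (tuple keys flattened to 'culture|condition')."""
        d = asdict(self)
        for key in ("viable_fraction", "outgrowth_fraction"):
            d[key] = {f"{c}|{cond}": v for (c, cond), v in d[key].items()}
        return d


def dose_response_viable_fraction(
    v0: float, dose: float, emax: float, ec50: float, hill: float
) -> float:
    """Expected viable fraction under an Emax/Hill dose-response model.

    Returns ``v0 * (1 - emax * dose^hill / (dose^hill + ec50^hill))``: the
    viable fraction declines monotonically from ``v0`` toward
    ``v0 * (1 - emax)`` with increasing dose, half-maximal inhibition at
    ``ec50``.

    Parameters
    ----------
    v0 : baseline viable fraction in [0, 1].
    dose : drug concentration in µM, >= 0.
    emax : maximal fractional reduction in [0, 1].
    ec50 : dose of half-maximal effect in µM, > 0.
    hill : Hill exponent, > 0.
    """
    if not (0.0 <= v0 <= 1.0):
        raise ValueError(f"v0 must be in [0, 1], got {v0}")
    if not (0.0 <= emax <= 1.0):
        raise ValueError(f"emax must be in [0, 1], got {emax}")
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if ec50 <= 0:
        raise ValueError(f"ec50 must be > 0, got {ec50}")
    if hill <= 0:
        raise ValueError(f"hill must be > 0, got {hill}")
    if dose == 0:
        return v0
    dh = float(dose) ** hill
    return v0 * (1.0 - emax * dh / (dh + float(ec50) ** hill))


def _noisy_fraction(expected: float, rng: np.random.Generator, noise_sd: float) -> float:
    """Logit-normal perturbation of a fraction; identity when noise_sd == 0."""
    if noise_sd == 0:
        return expected
    p = min(max(expected, _LOGIT_EPS), 1.0 - _LOGIT_EPS)
    return float(expit(logit(p) + rng.normal(0.0, noise_sd)))


def _split_lengths(
    total: float, n_parts: int, rng: np.random.Generator
) -> np.ndarray:
    """Split ``total`` into ``n_parts`` via a symmetric Dirichlet composition.

    The last part is computed as a residual so the parts sum to ``total``
    exactly in floating point.
    """
    if n_parts == 1:
        return np.array([total])
    w = rng.dirichlet(np.ones(n_parts))
    parts = w * total
    parts[-1] = total - parts[:-1].sum()
    return parts


def _expected_fractions(
    v0: float, cond: ConditionSpec, cfg: SyntheticConfig, responder: bool
) -> tuple[float, float]:
    """Expected (viable, outgrowth) fraction for one patient x condition."""
    if cond.selenite:
        frac = 0.0
        if cond.dose_um > 0:
            dh = cond.dose_um ** cfg.hill
            frac = dh / (dh + cfg.ec50_um ** cfg.hill)
        viable = v0 * (1.0 - cfg.emax * frac)
        outgrowth = cfg.outgrowth0 * (1.0 - cfg.outgrowth_decline * frac)
    else:
        # Non-selenite arm (gemcitabine): responders get the maximal effect,
        # non-responders are unchanged from baseline.
        if responder:
            viable = v0 * (1.0 - cfg.emax)
            outgrowth = cfg.outgrowth0 * (1.0 - cfg.outgrowth_decline)
        else:
            viable = v0
            outgrowth = cfg.outgrowth0
    return viable, outgrowth


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a synthetic annotation-measurement cohort.

    Returns a tidy annotation table (one row per measured annotation, columns
    ``culture_id, slice_id, replicate, condition, dose_um, annotation_class,
    measure_kind, value, unit``) plus the :class:`GroundTruth` it was drawn
    from.  Identical config and seed give byte-identical tables; per-patient
    RNG substreams are spawned as ``SeedSequence([seed, patient_index])`` so
    enlarging the cohort never reshuffles earlier patients.
    """
    cfg = config
    truth = GroundTruth()
    rows: list[dict] = []

    for i in range(cfg.n_patients):
        culture = f"DT{i + 1}"
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        v0 = float(rng.beta(cfg.v0_alpha, cfg.v0_beta))
        responder = bool(rng.random() < cfg.gem_responder_prob)
        # Area-mode patients occupy the tail of the roster.
        area_mode = i >= cfg.n_patients - cfg.area_mode_patients
        truth.v0[culture] = v0
        truth.gem_responder[culture] = responder
        truth.mode[culture] = "area" if area_mode else "outgrowth"

        for cond in cfg.conditions:
            v_exp, o_exp = _expected_fractions(v0, cond, cfg, responder)
            truth.viable_fraction[(culture, cond.label)] = v_exp
            truth.outgrowth_fraction[(culture, cond.label)] = o_exp

            for rep in range(1, cfg.duplicates_per_condition + 1):
                slice_id = f"{culture}_{cond.label}_s{rep}"
                v_s = _noisy_fraction(v_exp, rng, cfg.noise_sd)
                if area_mode:
                    total_area = float(
                        rng.lognormal(np.log(5e6), 0.2)
                    )  # µm² of annotated tumor per slice
                    viable_area = total_area * v_s
                    damaged_area = total_area - viable_area
                    rows.append(
                        _row(culture, slice_id, rep, cond, "tumor_viable_area",
                             "area", viable_area, "um2")
                    )
                    rows.append(
                        _row(culture, slice_id, rep, cond, "tumor_damaged_area",
                             "area", damaged_area, "um2")
                    )
                else:
                    o_s = _noisy_fraction(o_exp, rng, cfg.noise_sd)
                    perimeter = float(rng.lognormal(np.log(cfg.perimeter_mean_um), 0.15))
                    outgrowth_len = perimeter * o_s
                    viable_len = outgrowth_len * v_s
                    damaged_len = outgrowth_len - viable_len
                    rows.append(
                        _row(culture, slice_id, rep, cond, "perimeter",
                             "perimeter", perimeter, "um")
                    )
                    for cls, length in zip(
                        VIABLE_CLASSES,
                        _split_lengths(viable_len, len(VIABLE_CLASSES), rng),
                    ):
                        rows.append(
                            _row(culture, slice_id, rep, cond, cls, "length",
                                 float(length), "um")
                        )
                    for cls, length in zip(
                        DAMAGED_CLASSES,
                        _split_lengths(damaged_len, len(DAMAGED_CLASSES), rng),
                    ):
                        rows.append(
                            _row(culture, slice_id, rep, cond, cls, "length",
                                 float(length), "um")
                        )

    table = pd.DataFrame(rows)
    return table, truth


def _row(culture, slice_id, rep, cond: ConditionSpec, cls, kind, value, unit) -> dict:
    return {
        "culture_id": culture,
        "slice_id": slice_id,
        "replicate": rep,
        "condition": cond.label,
        "dose_um": cond.dose_um,
        "annotation_class": cls,
        "measure_kind": kind,
        "value": value,
        "unit": unit,
    }


def generate_de_table(
    n_genes: int,
    n_signal: int,
    effect_log2fc: float = 2.0,
    seed: int = 0,
    mean_log_reads: float = np.log(800.0),
    sd_log_reads: float = 1.6,
) -> pd.DataFrame:
    """Generate a differential-expression results table.

    Null genes carry ~N(0, 0.15) log2 fold changes and uniform p-values;
    signal genes carry |log2FC| >= ``effect_log2fc`` with random sign and
    p-values between 1e-12 and ~3e-5.  Aligned read counts are log-normal
    (long-tailed), so with the default scale roughly a third of transcripts
    fall below 350 reads.  Adjusted p-values are Benjamini-Hochberg over the
    whole table.
    """
    if n_genes < 0 or n_signal < 0:
        raise ValueError("gene counts must be non-negative")
    if n_signal > n_genes:
        raise ValueError("n_signal cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    n_null = n_genes - n_signal

    log2fc = np.concatenate(
        [
            rng.choice([-1.0, 1.0], n_signal)
            * (effect_log2fc + np.abs(rng.normal(0.0, 0.3, n_signal))),
            rng.normal(0.0, 0.15, n_null),
        ]
    )
    p = np.concatenate(
        [10.0 ** rng.uniform(-12.0, -4.5, n_signal), rng.uniform(0.0, 1.0, n_null)]
    )
    reads = np.floor(rng.lognormal(mean_log_reads, sd_log_reads, n_genes)).astype(int)

    from .stats import bh_adjust  # local import avoids a cycle at module load

    table = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "total_reads": reads,
            "log2fc": log2fc,
            "p_value": p,
            "p_adjusted": bh_adjust(p) if n_genes else np.array([]),
        }
    )
    return table
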