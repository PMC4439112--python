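"""Per-gene repression, RISC-IP enrichment, and combined target scores.

The experiment profiles four library classes — expression and RISC
immunoprecipitation (RIP), each under a miRNA transfection (treatment) and
a control transfection — with biological replicates.  Per gene, with
replicate-mean, floored FPKM-like abundances:

    repression  R = expr_control / expr_treatment
    enrichment  E = (rip_treatment / expr_treatment)
                  / (rip_control   / expr_control)
    score       S = (E + R) / 2

R > 1 means the gene is lower after miRNA transfection; E > 1 means
miRNA-dependent RISC association.  Genes with S >= 1.5 form the target
set.  Abundances below 1 are floored to 1 to avoid denominator inflation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RipseedError

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 1.0
DEFAULT_THRESHOLD = 1.5

ASSAYS = ("expression", "rip")
CONDITIONS = ("treatment", "control")

#: (assay, condition) -> summary column name
CLASS_COLUMNS = {
    ("expression", "treatment"): "expr_trt",
    ("expression", "control"): "expr_ctl",
    ("rip", "treatment"): "rip_trt",
    ("rip", "control"): "rip_ctl",
}


@dataclass(frozen=True)
class AbundanceMatrix:
    """Gene x sample abundance table (FPKM-like, nonnegative)."""

    values: pd.DataFrame
    floored: bool = False

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise RipseedError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            raise RipseedError("duplicate sample columns")
        arr = v.to_numpy(dtype=float, copy=False)
        if np.any(arr[np.isfinite(arr)] < 0):
            raise RipseedError("abundances must be nonnegative")


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-design sheet: columns, vocabulary, class coverage."""
    required = {"sample_id", "assay", "condition", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ConfigurationError(f"design sheet missing columns: {sorted(missing)}")
    d = design.copy()
    bad_assay = set(d["assay"]) - set(ASSAYS)
    if bad_assay:
        raise ConfigurationError(f"unknown assay values: {sorted(bad_assay)}")
    bad_cond = set(d["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ConfigurationError(f"unknown condition values: {sorted(bad_cond)}")
    trips = d[["assay", "condition", "replicate"]]
    if trips.duplicated().any():
        raise ConfigurationError("duplicate (assay, condition, replicate) triple")
    if d["sample_id"].duplicated().any():
        raise ConfigurationError("duplicate sample_id in design")
    present = set(zip(d["assay"], d["condition"]))
    absent = set(CLASS_COLUMNS) - present
    if absent:
        raise ConfigurationError(
            f"design lacks sample classes: {sorted(absent)}"
        )
    return d


def floor_abundances(
    matrix: AbundanceMatrix, floor: float = DEFAULT_FLOOR
) -> AbundanceMatrix:
    """Replace every value below ``floor`` with ``floor`` (idempotent)."""
    return AbundanceMatrix(matrix.values.clip(lower=floor), floored=True)


def summarize_conditions(
    matrix: AbundanceMatrix,
    design: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Replicate-mean abundance per (assay, condition), then floored.

    Returns a per-gene frame with columns expr_trt / expr_ctl / rip_trt /
    rip_ctl.  Genes with a missing (NaN) value in any class are dropped
    and logged.
    """
    d = validate_design(design)
    absent = [s for s in d["sample_id"] if s not in matrix.values.columns]
    if absent:
        raise ConfigurationError(
            f"design samples missing from abundance table: {absent}"
        )
    out = {}
    for (assay, cond), col in CLASS_COLUMNS.items():
        samples = d.loc[
            (d["assay"] == assay) & (d["condition"] == cond), "sample_id"
        ].tolist()
        out[col] = matrix.values[samples].mean(axis=1)
    summary = pd.DataFrame(out).clip(lower=floor)
    dropped = summary.index[summary.isna().any(axis=1)]
    if len(dropped):
        logger.warning(
            "dropping %d genes with missing class abundances (e.g. %s)",
            len(dropped), list(dropped[:5]),
        )
        summary = summary.drop(index=dropped)
    return summary


def repression(summary: pd.DataFrame) -> pd.Series:
    """R = expr_control / expr_treatment; > 1 means knocked down."""
    r = summary["expr_ctl"] / summary["expr_trt"]
    return r.rename("repression")


def rip_enrichment(summary: pd.DataFrame) -> pd.Series:
    """E = (rip_trt/expr_trt) / (rip_ctl/expr_ctl).

    RIP abundances are normalized to expression first, so E measures
    treatment-dependent RISC association, not expression change.
    """
    e = (summary["rip_trt"] / summary["expr_trt"]) / (
        summary["rip_ctl"] / summary["expr_ctl"]
    )
    return e.rename("enrichment")


def target_score(enrichment: pd.Series, repression: pd.Series) -> pd.Series:
    """S = (E + R) / 2 on the genes where both are defined."""
    common = enrichment.index.intersection(repression.index)
    n_lost = max(len(enrichment), len(repression)) - len(common)
    if n_lost:
        logger.warning("%d genes lack E or R and are excluded from scoring", n_lost)
    e, r = enrichment.loc[common], repression.loc[common]
    if (e <= 0).any() or (r <= 0).any():
        raise RipseedError("enrichment and repression must be positive")
    return ((e + r) / 2.0).rename("score")


def call_targets(
    enrichment: pd.Series,
    repression: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Score every gene and call targets at S >= threshold (inclusive).

    Returns a frame indexed by gene_id with columns repression,
    enrichment, score, is_target; ordered by descending score, ties broken
    by ascending gene_id.
    """
    s = target_score(enrichment, repression)
    tbl = pd.DataFrame(
        {
            "repression": repression.loc[s.index],
            "enrichment": enrichment.loc[s.index],
            "score": s,
            "is_target": s >= threshold,
        }
    )
    # descending score, ties broken by ascending gene id
    tbl = tbl.iloc[
        np.lexsort((tbl.index.to_numpy(), -tbl["score"].to_numpy()))
    ]
    tbl.index.name = "gene_id"
    return tbl


def score_pipeline(
    matrix: AbundanceMatrix,
    design: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Abundances + design -> scored target table (convenience wrapper)."""
    summary = summarize_conditions(matrix, design, floor=floor)
    return call_targets(rip_enrichment(summary), repression(summary), threshold)
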