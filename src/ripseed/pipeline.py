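"""End-to-end report: scan -> score -> bins -> regions -> tiling.

Holds the run configuration (whose defaults are the analysis constants:
floor 1, score threshold 1.5, bin size 250, 7-mer seed from guide
position 2) and the orchestration used by both the CLI ``report``
subcommand and the acceptance script.  All outputs are deterministic
functions of (inputs, config).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import profile_analysis as pa
from . import scoring, stats
from .errors import InsufficientDataError, RipseedError, UndefinedRatioError
from .seed_scan import (
    CDS,
    MIR191,
    REGIONS,
    UTR3,
    UTR5,
    GeneModel,
    MatureMiRNA,
    annotate_gene_matches,
    derive_seed_match_kmer,
    tiling_windows,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants; defaults are the pipeline's canonical values."""

    mirna_name: str = MIR191.name
    guide_sequence: str = MIR191.guide_sequence
    seed_start: int = 2
    seed_k: int = 7
    floor: float = scoring.DEFAULT_FLOOR
    threshold: float = scoring.DEFAULT_THRESHOLD
    bin_size: int = pa.DEFAULT_BIN_SIZE
    tiling_k: int = 6
    comparison_mode: str = "exclusive"  # gene grouping for region comparisons
    log2_transform: bool = True

    def mirna(self) -> MatureMiRNA:
        return MatureMiRNA(self.mirna_name, self.guide_sequence)

    def seed(self):
        return derive_seed_match_kmer(self.mirna(), self.seed_start, self.seed_k)


@dataclass
class ReportResult:
    """All plot-ready tables produced by one report run."""

    matches: pd.DataFrame
    scores: pd.DataFrame
    bins: pd.DataFrame
    region_proportions: pd.DataFrame
    comparisons: pd.DataFrame
    tiling: pd.DataFrame
    summary: dict


def _comparison_row(
    label_a: str, label_b: str, statistic: str, res: stats.GroupComparison
) -> dict:
    return {
        "statistic": statistic,
        "groupA": label_a,
        "groupB": label_b,
        "nA": res.n_a,
        "nB": res.n_b,
        "meanA": res.mean_a,
        "meanB": res.mean_b,
        "t": res.t,
        "df": res.df,
        "p": res.p,
        "alternative": res.alternative,
    }


def run_report(
    genes: Sequence[GeneModel],
    matrix: scoring.AbundanceMatrix,
    design: pd.DataFrame,
    config: RunConfig = RunConfig(),
) -> ReportResult:
    """Run the full target-profiling analysis on one study.

    Scans every transcript for the seed match, scores every gene profiled
    in the abundance tables, and derives the validation profiles (ranked
    bins, region proportions and comparisons, guide tiling) on the genes
    present in both inputs.
    """
    from .io import matches_to_frame  # local import to avoid cycle

    seed = config.seed()
    gene_by_id = {g.gene_id: g for g in genes}
    if len(gene_by_id) != len(genes):
        raise RipseedError("duplicate gene ids in gene models")

    all_matches = [m for g in genes for m in annotate_gene_matches(g, seed)]
    scores = scoring.score_pipeline(
        matrix, design, floor=config.floor, threshold=config.threshold
    )

    universe = [gid for gid in scores.index if gid in gene_by_id]
    n_unmodeled = len(scores) - len(universe)
    if n_unmodeled:
        logger.warning(
            "%d profiled genes lack gene models; excluded from seed analyses",
            n_unmodeled,
        )
    flags = pa.region_flags(
        [m for m in all_matches if m.gene_id in set(universe)], universe
    )
    targets = [g for g in universe if scores.loc[g, "is_target"]]

    # ranked-bin seed frequency: 3'UTR matches over the score ranking
    ranked = pa.rank_genes(scores.loc[universe, "score"])
    try:
        bins = pa.binned_seed_frequency(
            list(ranked), flags[UTR3], bin_size=config.bin_size, background=universe
        )
    except UndefinedRatioError:
        logger.warning("no 3'UTR seed matches in the universe; bin profile empty")
        bins = pd.DataFrame(
            columns=["bin_index", "bin_size", "n_match", "relative_frequency",
                     "partial"]
        )

    # region proportions for both universes and both modes
    prop_rows = []
    for label, members in (("all_profiled", universe), ("target_set", targets)):
        if not members:
            continue
        sub = flags.loc[members]
        for mode in ("inclusive", "exclusive"):
            tbl = pa.region_proportions(sub, mode=mode)
            tbl.insert(0, "universe", label)
            tbl.insert(1, "mode", mode)
            prop_rows.append(tbl)
    proportions = (
        pd.concat(prop_rows, ignore_index=True) if prop_rows else pd.DataFrame()
    )

    # region-stratified distribution comparisons (CDS vs UTRs)
    if config.comparison_mode == "exclusive":
        cat = pa.exclusive_region_membership(flags)
        groups = {r: cat == r for r in REGIONS}
    else:
        groups = {r: flags[r] for r in REGIONS}
    comp_rows = []
    for stat_name, col in (("log2_repression", "repression"),
                           ("log2_enrichment", "enrichment")):
        vals = scores.loc[universe, col]
        vals = np.log2(vals) if config.log2_transform else vals
        for ra, rb in ((CDS, UTR3), (CDS, UTR5)):
            try:
                res = pa.region_distribution_compare(
                    vals, groups[ra], groups[rb],
                    alternative=stats.TWO_SIDED, label_a=ra, label_b=rb,
                )
            except InsufficientDataError as exc:
                logger.warning("skipping %s %s vs %s: %s", stat_name, ra, rb, exc)
                continue
            comp_rows.append(_comparison_row(ra, rb, stat_name, res.result))
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["statistic", "groupA", "groupB", "nA", "nB", "meanA", "meanB",
                 "t", "df", "p", "alternative"],
    )

    # 6-mer tiling across the guide, target set vs all profiled
    utr3_seqs = {g: gene_by_id[g].region_sequence(UTR3) for g in universe}
    windows = tiling_windows(config.mirna(), k=config.tiling_k)
    if targets:
        tiling = pa.tiling_relative_frequency(windows, targets, universe, utr3_seqs)
    else:
        logger.warning("empty target set; tiling profile skipped")
        tiling = pd.DataFrame(
            columns=["guide_start", "guide_window", "match_kmer",
                     "relative_frequency"]
        )

    summary = {
        "config": asdict(config),
        "match_kmer": seed.match_kmer,
        "n_gene_models": len(genes),
        "n_genes_scored": len(scores),
        "n_genes_analyzed": len(universe),
        "n_genes_without_model": n_unmodeled,
        "n_seed_matches": len(all_matches),
        "n_targets_called": len(targets),
    }
    return ReportResult(
        matches=matches_to_frame(all_matches),
        scores=scores,
        bins=bins,
        region_proportions=proportions,
        comparisons=comparisons,
        tiling=tiling,
        summary=summary,
    )
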