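"""Seed-centric validation analyses over ranked or grouped gene sets.

If the scoring pipeline really captures miRNA targeting, seed matches
should concentrate where the scores say the targets are.  This module
implements the checks: relative seed-match frequency across consecutive
ranked bins of genes, region-stratified (5'UTR/CDS/3'UTR) proportions and
distribution comparisons, ECDFs for group overlays, and a k-mer tiling
scan across the whole guide that asks whether transcript complementarity
is specific to the seed window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as _stats
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    RipseedError,
    UndefinedRatioError,
)
from .seed_scan import REGIONS, SeedMatchRecord, TilingWindow, scan_sequence

DEFAULT_BIN_SIZE = 250


def rank_genes(values: pd.Series, direction: str = "descending") -> pd.Index:
    """Order genes by value; ties broken by ascending gene id.

    ``direction='descending'`` puts the largest value (most enriched /
    most repressed / highest score) first.
    """
    if direction not in ("descending", "ascending"):
        raise RipseedError(f"unknown direction {direction!r}")
    v = values.astype(float)
    if v.isna().any():
        bad = list(v.index[v.isna()][:5])
        raise RipseedError(f"ranking values contain NaN (e.g. {bad})")
    key = -v.to_numpy() if direction == "descending" else v.to_numpy()
    order = np.lexsort((v.index.to_numpy(), key))
    return v.index[order]


def binned_seed_frequency(
    ranked: Sequence[str],
    has_match: Mapping[str, bool] | pd.Series,
    bin_size: int = DEFAULT_BIN_SIZE,
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Relative seed-match frequency in consecutive rank bins.

    Genes are cut into consecutive non-overlapping bins of ``bin_size`` in
    rank order (last bin may be partial, flagged).  Each bin's
    ``relative_frequency`` is its fraction of genes with a seed match
    divided by the same fraction over the ``background`` universe
    (default: the ranked genes themselves).
    """
    if bin_size < 1:
        raise RipseedError("bin_size must be >= 1")
    ranked = list(ranked)
    if not ranked:
        raise RipseedError("ranked gene list is empty")
    hm = pd.Series(has_match).astype(bool)
    bg = list(background) if background is not None else ranked
    for g in ranked:
        if g not in hm.index:
            raise ConfigurationError(f"no has_match value for ranked gene {g!r}")
    bg_frac = float(hm.loc[bg].mean())
    if bg_frac == 0.0:
        raise UndefinedRatioError(
            "background seed-match fraction is 0; relative frequency undefined "
            "— choose a background universe containing matched genes"
        )
    rows = []
    for i in range(0, len(ranked), bin_size):
        chunk = ranked[i : i + bin_size]
        n_match = int(hm.loc[chunk].sum())
        frac = n_match / len(chunk)
        rows.append(
            {
                "bin_index": i // bin_size + 1,
                "bin_size": len(chunk),
                "n_match": n_match,
                "relative_frequency": frac / bg_frac,
                "partial": len(chunk) < bin_size,
            }
        )
    return pd.DataFrame(rows)


def region_flags(
    matches: Iterable[SeedMatchRecord], universe: Iterable[str]
) -> pd.DataFrame:
    """Per-gene booleans: has >= 1 seed match in each region.

    Indexed by the gene universe; a match for a gene outside the universe
    is a consistency error.
    """
    idx = pd.Index(list(universe), name="gene_id")
    if idx.has_duplicates:
        raise RipseedError("duplicate gene ids in universe")
    flags = pd.DataFrame(False, index=idx, columns=list(REGIONS))
    for m in matches:
        if m.gene_id not in flags.index:
            raise ConfigurationError(
                f"match for gene {m.gene_id!r} not in the universe"
            )
        flags.loc[m.gene_id, m.region] = True
    return flags


def exclusive_region_membership(flags: pd.DataFrame) -> pd.Series:
    """Categorize genes: one of UTR5/CDS/UTR3, 'multiple', or 'none'."""
    n_regions = flags[list(REGIONS)].sum(axis=1)
    cat = pd.Series("none", index=flags.index, name="region_category")
    cat[n_regions > 1] = "multiple"
    for region in REGIONS:
        only = flags[region] & (n_regions == 1)
        cat[only] = region
    return cat


def region_proportions(
    flags: pd.DataFrame, mode: str = "inclusive"
) -> pd.DataFrame:
    """Gene counts/proportions per seed-match region over the universe.

    inclusive: a gene counts in every region where it has a match (rows
    may overlap).  exclusive: only single-region genes count in a region;
    'multiple' and 'none' rows make the counts partition the universe.
    """
    n = len(flags)
    if n == 0:
        raise RipseedError("empty universe")
    rows = []
    if mode == "inclusive":
        for region in REGIONS:
            c = int(flags[region].sum())
            rows.append({"category": region, "n_genes": c, "proportion": c / n})
    elif mode == "exclusive":
        cat = exclusive_region_membership(flags)
        for category in list(REGIONS) + ["multiple", "none"]:
            c = int((cat == category).sum())
            rows.append({"category": category, "n_genes": c, "proportion": c / n})
    else:
        raise RipseedError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def ecdf(values) -> pd.DataFrame:
    """Right-continuous empirical CDF points (value, cumulative_fraction)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise RipseedError("ecdf needs at least one finite value")
    xs, counts = np.unique(arr, return_counts=True)
    return pd.DataFrame(
        {"value": xs, "cumulative_fraction": np.cumsum(counts) / arr.size}
    )


@dataclass(frozen=True)
class RegionComparison:
    """Welch comparison of a per-gene statistic between two gene groups."""

    group_a: str
    group_b: str
    result: _stats.GroupComparison


def region_distribution_compare(
    values: pd.Series,
    group_a: pd.Series,
    group_b: pd.Series,
    alternative: str = _stats.TWO_SIDED,
    label_a: str = "A",
    label_b: str = "B",
) -> RegionComparison:
    """Welch t-test of ``values`` (e.g. log2 E or log2 R) between groups.

    ``group_a``/``group_b`` are boolean per-gene masks, typically built
    from :func:`region_flags` / :func:`exclusive_region_membership`.
    """
    a = values[group_a.reindex(values.index, fill_value=False)]
    b = values[group_b.reindex(values.index, fill_value=False)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"groups of size {len(a)} and {len(b)}; need >= 2 each"
        )
    return RegionComparison(label_a, label_b, _stats.welch_t_test(a, b, alternative))


def tiling_relative_frequency(
    windows: Sequence[TilingWindow],
    target_set: Iterable[str],
    background: Iterable[str],
    utr3_sequences: Mapping[str, str],
) -> pd.DataFrame:
    """Per guide window, target-vs-background 3'UTR match-k-mer frequency.

    For each window of the guide (from :func:`seed_scan.tiling_windows`)
    the relative frequency is the fraction of target-set genes whose 3'UTR
    contains the window's match k-mer, divided by the same fraction over
    the background.  A window absent from every background 3'UTR gets NaN
    rather than aborting the scan.
    """
    targets = list(target_set)
    bg = list(background)
    if not targets:
        raise RipseedError("target set is empty")
    if not bg:
        raise RipseedError("background set is empty")
    for g in targets + bg:
        if g not in utr3_sequences:
            raise ConfigurationError(f"no 3'UTR sequence for gene {g!r}")
    rows = []
    for w in windows:
        def frac(genes):
            n = sum(
                1 for g in genes if scan_sequence(utr3_sequences[g], w.match_kmer)
            )
            return n / len(genes)

        bg_frac = frac(bg)
        rel = frac(targets) / bg_frac if bg_frac > 0 else float("nan")
        rows.append(
            {
                "guide_start": w.guide_start,
                "guide_window": w.guide_window,
                "match_kmer": w.match_kmer,
                "relative_frequency": rel,
            }
        )
    return pd.DataFrame(rows)
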