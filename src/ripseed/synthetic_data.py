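"""Synthetic transcriptomes and RIP/expression abundance tables.

Generates a study with known ground truth so every pipeline stage can be
checked by parameter recovery: random transcripts partitioned into
5'UTR/CDS/3'UTR, a chosen subset of "true target" genes carrying a planted
seed-match site, and four-class abundance tables (expression / RIP x
treatment / control, replicated) in which true targets receive a
multiplicative RIP enrichment and expression knockdown on top of a
log-normal baseline, with log-normal replicate noise.

The noise model is the generator's own: effects are multiplicative on
expectations and replicate noise is log-normal, matching the ratio-based
downstream analysis and the heavy-tailed behavior of FPKM data.  Defaults
describe the simulated study the package's recovery checks run on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scoring import CLASS_COLUMNS, AbundanceMatrix
from .seed_scan import (
    CDS,
    MIR191,
    REGIONS,
    UTR3,
    UTR5,
    GeneModel,
    MatureMiRNA,
    SeedDefinition,
    derive_seed_match_kmer,
    scan_sequence,
)

_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_TRIES = 200


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated profiling experiment.

    Lengths are mean region lengths in nt (each gene draws uniformly in
    +/-30% of the mean); abundances are FPKM-like.  ``enrichment_fold``
    multiplies RIP/treatment and ``repression_fold`` divides
    expression/treatment for true targets, so the expected per-target
    enrichment E and repression R equal the two folds whenever baselines
    sit above the floor.
    """

    n_genes: int = 10_000
    n_true_targets: int = 500
    utr5_mean_length: int = 150
    cds_mean_length: int = 1000
    utr3_mean_length: int = 700
    gc_content: float = 0.5
    seed_plant_region: str = UTR3
    region_weights: tuple[float, float, float] = (0.0, 0.0, 1.0)  # UTR5, CDS, UTR3
    enrichment_fold: float = 3.0
    repression_fold: float = 2.0
    baseline_median: float = 30.0
    baseline_log_sd: float = 1.0
    replicate_noise_sd: float = 0.25
    n_replicates: int = 3
    background_site_rate: float = 0.0
    rip_background_fold: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_true_targets <= self.n_genes:
            raise ConfigurationError("n_true_targets must be in [0, n_genes]")
        if self.enrichment_fold <= 1.0 or self.repression_fold <= 1.0:
            raise ConfigurationError("effect folds must exceed 1")
        if self.replicate_noise_sd < 0 or self.baseline_log_sd < 0:
            raise ConfigurationError("noise sigmas must be >= 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigurationError("gc_content must be in (0, 1)")
        if self.seed_plant_region not in REGIONS + ("mixed",):
            raise ConfigurationError(
                f"seed_plant_region must be one of {REGIONS + ('mixed',)}"
            )
        if self.n_replicates < 1:
            raise ConfigurationError("need >= 1 replicate per class")


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    region: str
    position: int  # 1-based transcript coordinate of the planted k-mer start


@dataclass(frozen=True)
class GroundTruth:
    """Planted targets, their sites, and expected per-gene E and R."""

    target_ids: tuple[str, ...]
    sites: tuple[PlantedSite, ...]
    expected: pd.DataFrame  # index gene_id; columns expected_E, expected_R


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASE_LOOKUP[codes].tobytes().decode("ascii")


def _region_lengths(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[int, int, int]:
    def draw(mean: int) -> int:
        lo, hi = int(round(mean * 0.7)), int(round(mean * 1.3))
        return int(rng.integers(lo, hi + 1))

    u5 = draw(config.utr5_mean_length)
    cds = max(1, draw(config.cds_mean_length))
    u3 = draw(config.utr3_mean_length)
    return u5, cds, u3


def _plant(
    rng: np.random.Generator,
    seq: str,
    region_span: tuple[int, int],
    kmer: str,
) -> tuple[str, int]:
    """Splice ``kmer`` into a uniform position within a region span.

    Returns the new sequence and the 1-based site start; retries positions
    whose junction flanks would create a second occurrence.
    """
    lo, hi = region_span
    k = len(kmer)
    if hi - lo + 1 < k:
        raise ConfigurationError(
            f"region of length {hi - lo + 1} too short to plant a {k}-mer"
        )
    for _ in range(_MAX_TRIES):
        pos = int(rng.integers(lo, hi - k + 2))  # 1-based start
        cand = seq[: pos - 1] + kmer + seq[pos - 1 + k :]
        if len(scan_sequence(cand, kmer)) == 1:
            return cand, pos
    raise ConfigurationError("could not plant a unique seed site")


def simulate_transcriptome(
    config: SimulationConfig,
    mirna: MatureMiRNA = MIR191,
    seed: SeedDefinition | None = None,
) -> tuple[list[GeneModel], GroundTruth]:
    """Random gene models with planted seed sites in the true targets.

    Non-target transcripts are rejection-sampled to contain no occurrence
    of the seed match k-mer anywhere (unless ``background_site_rate``
    re-introduces chance sites); each true target carries exactly one
    planted site at a uniform position within the configured region.
    Deterministic for a fixed ``rng_seed``.
    """
    if seed is None:
        seed = derive_seed_match_kmer(mirna)
    rng = np.random.default_rng(config.rng_seed)
    kmer = seed.match_kmer
    n_targets = config.n_true_targets
    width = len(str(config.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    # targets are a random subset so target status is independent of id order
    target_idx = set(
        rng.choice(config.n_genes, size=n_targets, replace=False).tolist()
    )

    genes: list[GeneModel] = []
    sites: list[PlantedSite] = []
    for i, gid in enumerate(gene_ids):
        u5, cds_len, u3 = _region_lengths(rng, config)
        total = u5 + cds_len + u3
        for _ in range(_MAX_TRIES):
            s = _random_sequence(rng, total, config.gc_content)
            if kmer not in s:
                break
        else:
            raise ConfigurationError("rejection sampling failed to avoid the seed")
        cds_start, cds_end = u5 + 1, u5 + cds_len
        spans = {
            UTR5: (1, u5),
            CDS: (cds_start, cds_end),
            UTR3: (cds_end + 1, total),
        }
        plant_here = i in target_idx
        if not plant_here and config.background_site_rate > 0:
            plant_here = bool(rng.random() < config.background_site_rate)
        if plant_here:
            if config.seed_plant_region == "mixed":
                w = np.asarray(config.region_weights, dtype=float)
                region = REGIONS[int(rng.choice(3, p=w / w.sum()))]
            else:
                region = config.seed_plant_region
            s, pos = _plant(rng, s, spans[region], kmer)
            if i in target_idx:
                sites.append(PlantedSite(gid, region, pos))
        genes.append(GeneModel(gid, s, cds_start, cds_end))

    target_ids = tuple(gid for i, gid in enumerate(gene_ids) if i in target_idx)
    expected = pd.DataFrame(
        {"expected_E": 1.0, "expected_R": 1.0},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    expected.loc[list(target_ids), "expected_E"] = config.enrichment_fold
    expected.loc[list(target_ids), "expected_R"] = config.repression_fold
    return genes, GroundTruth(target_ids, tuple(sites), expected)


def simulate_abundances(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruth,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Four-class replicated abundance tables for the simulated genes.

    Per gene, a log-normal baseline b (median ``baseline_median``); class
    expectations are b everywhere except, for true targets,
    expression/treatment = b / repression_fold and RIP/treatment =
    (b / repression_fold) * enrichment_fold — RIP abundance tracks the
    repressed transcript level times the fold-change in RISC loading, so
    the expression-normalized enrichment E recovers ``enrichment_fold``
    exactly in the noise-free limit.  RIP/control is scaled by
    ``rip_background_fold`` for targets to model treatment-independent
    RISC loading (1 = none).  Each replicate multiplies its expectation by
    exp(N(0, replicate_noise_sd^2)).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 1]).generate_state(1)[0]
    )
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    is_target = np.isin(np.array(gene_ids), np.array(truth.target_ids))
    baseline = config.baseline_median * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=n)
    )
    expectation = {
        "expr_trt": np.where(is_target, baseline / config.repression_fold, baseline),
        "expr_ctl": baseline,
        "rip_trt": np.where(
            is_target,
            baseline * config.enrichment_fold / config.repression_fold,
            baseline,
        ),
        "rip_ctl": np.where(
            is_target, baseline * config.rip_background_fold, baseline
        ),
    }
    columns: dict[str, np.ndarray] = {}
    design_rows = []
    for (assay, cond), cls in CLASS_COLUMNS.items():
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{assay}_{cond}_{rep}"
            noise = (
                np.exp(rng.normal(0.0, config.replicate_noise_sd, size=n))
                if config.replicate_noise_sd > 0
                else 1.0
            )
            columns[sample_id] = expectation[cls] * noise
            design_rows.append(
                {
                    "sample_id": sample_id,
                    "assay": assay,
                    "condition": cond,
                    "replicate": rep,
                }
            )
    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return AbundanceMatrix(values), pd.DataFrame(design_rows)


@dataclass(frozen=True)
class SimulatedStudy:
    config: SimulationConfig
    mirna: MatureMiRNA
    seed: SeedDefinition
    genes: list[GeneModel]
    truth: GroundTruth
    abundances: AbundanceMatrix
    design: pd.DataFrame


def simulate_study(
    config: SimulationConfig,
    mirna: MatureMiRNA = MIR191,
    seed: SeedDefinition | None = None,
) -> SimulatedStudy:
    """Transcriptome + abundances in one call (shared ``rng_seed``)."""
    if seed is None:
        seed = derive_seed_match_kmer(mirna)
    genes, truth = simulate_transcriptome(config, mirna, seed)
    abundances, design = simulate_abundances(config, genes, truth)
    return SimulatedStudy(config, mirna, seed, genes, truth, abundances, design)
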