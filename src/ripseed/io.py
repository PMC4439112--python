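"""Readers and writers for all interchange formats.

Everything is plain text: transcript FASTA plus a CDS-coordinate TSV for
gene models, and tab-separated tables (header row, UTF-8, '.' decimal) for
abundances, sample designs, seed matches, scores, profiles and ground
truth.  Floats are serialized at full precision so writer/reader pairs
round-trip losslessly and repeated runs are byte-identical.  Readers
validate strictly and raise :class:`~ripseed.errors.FormatError` naming
the file and the offending record.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FormatError
from .scoring import AbundanceMatrix, validate_design
from .seed_scan import GeneModel, SeedMatchRecord
from .synthetic_data import GroundTruth, PlantedSite

_FASTA_WIDTH = 60


# ---------------------------------------------------------------------------
# gene models: FASTA + region TSV

def read_transcript_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA -> {gene_id: sequence}; header token 1 is the gene id."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"{path}: duplicate gene id {record.id!r}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_transcript_fasta(
    sequences: Mapping[str, str], path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid, seq in sequences.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_region_table(path: str | os.PathLike) -> pd.DataFrame:
    """TSV `gene_id  cds_start  cds_end` (1-based inclusive)."""
    tbl = _read_tsv(path, ["gene_id", "cds_start", "cds_end"])
    if tbl["gene_id"].duplicated().any():
        dup = tbl.loc[tbl["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    for col in ("cds_start", "cds_end"):
        try:
            tbl[col] = tbl[col].astype(int)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-integer {col}: {exc}") from exc
    return tbl


def read_gene_models(
    fasta_path: str | os.PathLike, region_path: str | os.PathLike
) -> list[GeneModel]:
    """Join FASTA sequences with CDS coordinates into validated GeneModels."""
    seqs = read_transcript_fasta(fasta_path)
    regions = read_region_table(region_path)
    missing = set(seqs) - set(regions["gene_id"])
    if missing:
        raise FormatError(
            f"{region_path}: no CDS coordinates for genes {sorted(missing)[:5]}"
        )
    extra = set(regions["gene_id"]) - set(seqs)
    if extra:
        raise FormatError(
            f"{region_path}: coordinates for genes absent from FASTA "
            f"{sorted(extra)[:5]}"
        )
    genes = []
    for row in regions.itertuples(index=False):
        try:
            genes.append(
                GeneModel(row.gene_id, seqs[row.gene_id], row.cds_start, row.cds_end)
            )
        except Exception as exc:
            raise FormatError(f"{region_path}: gene {row.gene_id!r}: {exc}") from exc
    return genes


def write_gene_models(
    genes: Sequence[GeneModel],
    fasta_path: str | os.PathLike,
    region_path: str | os.PathLike,
) -> None:
    write_transcript_fasta(
        {g.gene_id: g.transcript_sequence for g in genes}, fasta_path
    )
    tbl = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "cds_start": [g.cds_start for g in genes],
            "cds_end": [g.cds_end for g in genes],
        }
    )
    _write_tsv(tbl, region_path)


# ---------------------------------------------------------------------------
# abundances + design

def read_abundance_table(path: str | os.PathLike) -> AbundanceMatrix:
    tbl = pd.read_csv(path, sep="\t", dtype={0: str})
    if tbl.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id'")
    tbl = tbl.set_index("gene_id")
    for col in tbl.columns:
        if not pd.api.types.is_numeric_dtype(tbl[col]):
            bad = tbl[pd.to_numeric(tbl[col], errors="coerce").isna()].index
            raise FormatError(
                f"{path}: non-numeric abundance in column {col!r} "
                f"(e.g. gene {bad[0]!r})"
            )
    try:
        return AbundanceMatrix(tbl.astype(float))
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_abundance_table(
    matrix: AbundanceMatrix, path: str | os.PathLike
) -> None:
    _write_tsv(matrix.values.reset_index(), path)


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    tbl = _read_tsv(path, ["sample_id", "assay", "condition", "replicate"])
    try:
        tbl["replicate"] = tbl["replicate"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer replicate: {exc}") from exc
    try:
        return validate_design(tbl)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_design(design: pd.DataFrame, path: str | os.PathLike) -> None:
    _write_tsv(design[["sample_id", "assay", "condition", "replicate"]], path)


# ---------------------------------------------------------------------------
# analysis outputs

def matches_to_frame(matches: Iterable[SeedMatchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "region": m.region,
                "position": m.position,
                "kmer": m.kmer,
                "spans_boundary": m.spans_boundary,
            }
            for m in matches
        ],
        columns=["gene_id", "region", "position", "kmer", "spans_boundary"],
    )


def write_matches(
    matches: Iterable[SeedMatchRecord], path: str | os.PathLike
) -> None:
    _write_tsv(matches_to_frame(matches), path)


def read_matches(path: str | os.PathLike) -> list[SeedMatchRecord]:
    tbl = _read_tsv(
        path, ["gene_id", "region", "position", "kmer", "spans_boundary"]
    )
    return [
        SeedMatchRecord(
            gene_id=row.gene_id,
            region=row.region,
            position=int(row.position),
            kmer=row.kmer,
            spans_boundary=_parse_bool(row.spans_boundary),
        )
        for row in tbl.itertuples(index=False)
    ]


def write_scores(scores: pd.DataFrame, path: str | os.PathLike) -> None:
    """Target table `gene_id repression enrichment score is_target`."""
    _write_tsv(scores.reset_index(), path)


def read_scores(path: str | os.PathLike) -> pd.DataFrame:
    tbl = _read_tsv(
        path, ["gene_id", "repression", "enrichment", "score", "is_target"]
    )
    tbl = tbl.set_index("gene_id")
    for col in ("repression", "enrichment", "score"):
        tbl[col] = tbl[col].astype(float)
    tbl["is_target"] = tbl["is_target"].map(_parse_bool).astype(bool)
    return tbl


def write_ground_truth(truth: GroundTruth, path: str | os.PathLike) -> None:
    site_by_gene = {s.gene_id: s for s in truth.sites}
    tbl = truth.expected.reset_index()
    tbl["is_true_target"] = tbl["gene_id"].isin(truth.target_ids)
    tbl["region"] = [
        site_by_gene[g].region if g in site_by_gene else ""
        for g in tbl["gene_id"]
    ]
    tbl["position"] = [
        site_by_gene[g].position if g in site_by_gene else ""
        for g in tbl["gene_id"]
    ]
    cols = ["gene_id", "is_true_target", "region", "position",
            "expected_E", "expected_R"]
    _write_tsv(tbl[cols], path)


def read_ground_truth(path: str | os.PathLike) -> GroundTruth:
    tbl = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "region": str})
    tbl["is_true_target"] = tbl["is_true_target"].map(_parse_bool)
    targets = tuple(tbl.loc[tbl["is_true_target"], "gene_id"])
    sites = tuple(
        PlantedSite(row.gene_id, row.region, int(row.position))
        for row in tbl.itertuples(index=False)
        if isinstance(row.region, str) and row.region
    )
    expected = tbl.set_index("gene_id")[["expected_E", "expected_R"]].astype(float)
    return GroundTruth(targets, sites, expected)


def write_table(tbl: pd.DataFrame, path: str | os.PathLike) -> None:
    """Generic TSV writer for bin/tiling/proportion/comparison tables."""
    _write_tsv(tbl, path)


# ---------------------------------------------------------------------------
# helpers

def _read_tsv(path: str | os.PathLike, required: list[str]) -> pd.DataFrame:
    try:
        tbl = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: unreadable TSV: {exc}") from exc
    missing = [c for c in required if c not in tbl.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return tbl


def _write_tsv(tbl: pd.DataFrame, path: str | os.PathLike) -> None:
    tbl.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise FormatError(f"cannot parse boolean {value!r}")
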