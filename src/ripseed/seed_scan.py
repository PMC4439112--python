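"""Seed-match derivation and transcript scanning.

A mature miRNA guide (RNA, 5'->3') loaded into RISC pairs to transcripts
through its seed region, guide positions ~2-8.  The transcript-side "seed
match" is the DNA reverse complement of that guide window.  This module
derives the match k-mer, locates every (possibly overlapping) occurrence in
a transcript, and classifies each occurrence into 5'UTR / CDS / 3'UTR by
the CDS coordinates of the gene model.  All coordinates are 1-based and
inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import AlphabetError, BoundsError

_BAD_RNA = re.compile(r"[^ACGUN]")
_BAD_DNA = re.compile(r"[^ACGTN]")

_COMPLEMENT = {
    "A": "T",
    "C": "G",
    "G": "C",
    "T": "A",
    "U": "A",
    "N": "N",
}

UTR5 = "UTR5"
CDS = "CDS"
UTR3 = "UTR3"
REGIONS = (UTR5, CDS, UTR3)


def normalize_sequence(seq: str, alphabet: str) -> str:
    """Uppercase and map U/T to the requested alphabet ('DNA' or 'RNA').

    Raises :class:`AlphabetError` naming the first offending symbol.
    """
    s = seq.upper()
    s = s.replace("T", "U") if alphabet == "RNA" else s.replace("U", "T")
    bad = (_BAD_RNA if alphabet == "RNA" else _BAD_DNA).search(s)
    if bad is not None:
        raise AlphabetError(seq[bad.start()], bad.start() + 1, alphabet)
    return s


def reverse_complement(seq: str, output_alphabet: str = "DNA") -> str:
    """Reverse complement of ``seq``, returned 5'->3' in DNA or RNA.

    Input may be DNA or RNA, any case; N maps to N.
    """
    if not seq:
        raise AlphabetError("", 1, output_alphabet)
    s = normalize_sequence(seq, "DNA")
    rc = "".join(_COMPLEMENT[ch] for ch in reversed(s))
    if output_alphabet == "RNA":
        rc = rc.replace("T", "U")
    return rc


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature guide-strand miRNA; sequence stored as RNA, 5'->3'."""

    name: str
    guide_sequence: str

    def __post_init__(self):
        object.__setattr__(
            self, "guide_sequence", normalize_sequence(self.guide_sequence, "RNA")
        )
        if "N" in self.guide_sequence:
            raise AlphabetError("N", self.guide_sequence.index("N") + 1, "RNA guide")
        if len(self.guide_sequence) < 8:
            raise BoundsError(
                f"guide {self.name!r} is {len(self.guide_sequence)} nt; need >= 8"
            )

    def __len__(self) -> int:
        return len(self.guide_sequence)


#: hsa-miR-191-5p guide strand, the miRNA this analysis was designed around.
MIR191 = MatureMiRNA("hsa-miR-191-5p", "CAACGGAAUCCCAAAAGCAGCUG")


@dataclass(frozen=True)
class SeedDefinition:
    """A guide window and its transcript-side match k-mer (DNA, 5'->3').

    The default elsewhere in the package is guide positions 2-8 (7mer-m8):
    a perfect reverse complement of the canonical seed region.
    """

    guide_start: int
    k: int
    match_kmer: str


def derive_seed_match_kmer(
    mirna: MatureMiRNA, guide_start: int = 2, k: int = 7
) -> SeedDefinition:
    """Reverse-complement the guide window [guide_start, guide_start+k-1].

    1-based positions on the guide; the returned ``match_kmer`` is the DNA
    k-mer whose occurrence in a transcript constitutes a seed match.
    """
    if guide_start < 1 or k < 1 or guide_start + k - 1 > len(mirna):
        raise BoundsError(
            f"window [{guide_start}, {guide_start + k - 1}] outside guide "
            f"of length {len(mirna)}"
        )
    window = mirna.guide_sequence[guide_start - 1 : guide_start - 1 + k]
    return SeedDefinition(guide_start, k, reverse_complement(window, "DNA"))


def scan_sequence(seq: str, kmer: str) -> list[int]:
    """All 1-based start positions of ``kmer`` in ``seq``, overlapping included.

    Windows containing N never match.  A kmer longer than the sequence
    yields an empty list.
    """
    s = normalize_sequence(seq, "DNA")
    q = normalize_sequence(kmer, "DNA")
    hits: list[int] = []
    start = s.find(q)
    while start != -1:
        if "N" not in s[start : start + len(q)]:
            hits.append(start + 1)
        start = s.find(q, start + 1)
    return hits


@dataclass(frozen=True)
class GeneModel:
    """A spliced transcript partitioned into 5'UTR / CDS / 3'UTR.

    ``cds_start``/``cds_end`` are 1-based inclusive transcript coordinates;
    UTR5 = [1, cds_start-1], CDS = [cds_start, cds_end],
    UTR3 = [cds_end+1, length].  Either UTR may be empty.
    """

    gene_id: str
    transcript_sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self):
        object.__setattr__(
            self,
            "transcript_sequence",
            normalize_sequence(self.transcript_sequence, "DNA"),
        )
        n = len(self.transcript_sequence)
        if not (1 <= self.cds_start <= self.cds_end <= n):
            raise BoundsError(
                f"gene {self.gene_id!r}: CDS [{self.cds_start}, {self.cds_end}] "
                f"invalid for transcript of length {n}"
            )

    def __len__(self) -> int:
        return len(self.transcript_sequence)

    def region_of(self, position: int) -> str:
        """Region containing a 1-based transcript position."""
        if not 1 <= position <= len(self):
            raise BoundsError(
                f"position {position} outside transcript of length {len(self)}"
            )
        if position < self.cds_start:
            return UTR5
        if position <= self.cds_end:
            return CDS
        return UTR3

    def region_sequence(self, region: str) -> str:
        s = self.transcript_sequence
        if region == UTR5:
            return s[: self.cds_start - 1]
        if region == CDS:
            return s[self.cds_start - 1 : self.cds_end]
        if region == UTR3:
            return s[self.cds_end :]
        raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class SeedMatchRecord:
    """One seed-match occurrence, classified by its start position."""

    gene_id: str
    region: str
    position: int  # 1-based transcript coordinate of match start
    kmer: str
    spans_boundary: bool = False


def annotate_gene_matches(
    gene: GeneModel, seed: SeedDefinition
) -> list[SeedMatchRecord]:
    """All occurrences of the seed match k-mer in a transcript, by region.

    A match is assigned to the region containing its START position; a
    match whose span crosses a region boundary keeps that assignment and is
    flagged ``spans_boundary``.
    """
    records = []
    for pos in scan_sequence(gene.transcript_sequence, seed.match_kmer):
        region = gene.region_of(pos)
        end_region = gene.region_of(min(pos + seed.k - 1, len(gene)))
        records.append(
            SeedMatchRecord(
                gene_id=gene.gene_id,
                region=region,
                position=pos,
                kmer=seed.match_kmer,
                spans_boundary=end_region != region,
            )
        )
    return records


@dataclass(frozen=True)
class TilingWindow:
    """One k-mer window of the guide and its transcript-side match k-mer."""

    guide_start: int
    guide_window: str
    match_kmer: str


def tiling_windows(mirna: MatureMiRNA, k: int = 6) -> list[TilingWindow]:
    """Every k-mer window of the guide, 5'->3', with its DNA match k-mer.

    Used to ask whether transcript-side complementarity is specific to the
    seed region: only windows inside the seed should be over-represented in
    true-target 3'UTRs.
    """
    if k > len(mirna) or k < 1:
        raise BoundsError(f"k={k} invalid for guide of length {len(mirna)}")
    out = []
    for start in range(1, len(mirna) - k + 2):
        window = mirna.guide_sequence[start - 1 : start - 1 + k]
        out.append(TilingWindow(start, window, reverse_complement(window, "DNA")))
    return out
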