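"""Genome/annotation parsing into per-gene transcript models.

The analysis keeps two separate region sets per gene — the 5' untranslated
region (5'UTR) and the main coding sequence (CDS) — because footprint reads
are counted against each set with different overlap semantics.  GFF3 input is
1-based closed; everything in memory is 0-based half-open.  Genes with
several isoforms are collapsed to one model per ``gene_id`` with overlapping
CDS intervals unioned, matching gene-level read counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval: ``start`` 0-based inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A gene's 5'UTR and CDS intervals plus spliced sequences.

    Interval lists are ordered 5'->3' in transcript orientation (on the minus
    strand the first interval has the highest genomic coordinates); sequences
    are spliced and already reverse-complemented where needed, so
    ``utr5_seq`` always starts at the transcript 5' end.
    """

    gene_id: str
    utr5: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5_seq: str = ""
    cds_seq: str = ""
    complete_cds: bool = False
    starts_with_atg: bool = False

    @property
    def chrom(self) -> str:
        return (self.cds or self.utr5)[0].chrom

    @property
    def strand(self) -> str:
        return (self.cds or self.utr5)[0].strand

    @property
    def utr5_len(self) -> int:
        return sum(len(iv) for iv in self.utr5)

    @property
    def cds_len(self) -> int:
        return sum(len(iv) for iv in self.cds)


@dataclass
class UtrAnnotationSource:
    """One published 5'UTR annotation set: gene_id -> interval list."""

    source_id: str
    records: dict[str, list[GenomicInterval]]

    def total_length(self, gene_id: str) -> int:
        return sum(len(iv) for iv in self.records[gene_id])


# ---------------------------------------------------------------------------
# sequence extraction


def _merge_union(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping/adjacent intervals; result sorted by genomic start."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: iv.start)
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom != last.chrom or iv.strand != last.strand:
            raise ValueError(f"intervals mix chrom/strand: {last} vs {iv}")
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


def transcript_order(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort intervals 5'->3' in transcript orientation."""
    if not intervals:
        return []
    rev = intervals[0].strand == "-"
    return sorted(intervals, key=lambda iv: iv.start, reverse=rev)


def spliced_sequence(intervals: list[GenomicInterval], genome: dict[str, str]) -> str:
    """Spliced sequence 5'->3' in transcript orientation (revcomp on minus)."""
    parts = []
    for iv in sorted(intervals, key=lambda iv: iv.start):
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome "
                f"(length {len(chrom_seq)})"
            )
        parts.append(chrom_seq[iv.start : iv.end].upper())
    seq = "".join(parts)
    if intervals and intervals[0].strand == "-":
        seq = revcomp(seq)
    return seq


def load_genome(fasta: "str | dict[str, str]") -> dict[str, str]:
    """Accept a FASTA path or an in-memory ``{chrom: sequence}`` mapping."""
    if isinstance(fasta, dict):
        return fasta
    from pyfaidx import Fasta

    with Fasta(fasta) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# GFF3 parsing


def _gene_id_of(feature) -> str | None:
    for key in ("gene_id", "Parent", "ID"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def parse_annotation(
    gff: str,
    genome: "str | dict[str, str]",
    cds_types: tuple[str, ...] = ("CDS",),
    utr_types: tuple[str, ...] = ("five_prime_UTR", "5UTR", "five_prime_utr"),
) -> dict[str, TranscriptModel]:
    """Parse GFF3 + genome into one :class:`TranscriptModel` per gene_id.

    ``gff`` may be a path or GFF3 text.  Genes without any 5'UTR feature get
    an empty ``utr5`` list.  A CDS whose spliced length is not a multiple of
    three is retained with ``complete_cds=False``, never dropped.
    """
    seqs = load_genome(genome)
    from_string = "\n" in gff or gff.lstrip().startswith("#")
    db = gffutils.create_db(
        gff,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )

    utr5: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    for feat in db.all_features():
        if feat.featuretype in cds_types:
            target = cds
        elif feat.featuretype in utr_types:
            target = utr5
        else:
            continue
        gid = _gene_id_of(feat)
        if gid is None:
            raise ValueError(f"feature without gene_id/Parent/ID: {feat}")
        if feat.seqid not in seqs:
            raise ValueError(
                f"unknown chromosome {feat.seqid!r} in feature line: {feat}"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if iv.end > len(seqs[iv.chrom]):
            raise ValueError(f"interval outside chromosome bounds: {feat}")
        target.setdefault(gid, []).append(iv)

    models: dict[str, TranscriptModel] = {}
    for gid in sorted(set(cds) | set(utr5)):
        cds_ivs = _merge_union(cds.get(gid, []))
        utr_ivs = _merge_union(utr5.get(gid, []))
        cds_seq = spliced_sequence(cds_ivs, seqs) if cds_ivs else ""
        utr_seq = spliced_sequence(utr_ivs, seqs) if utr_ivs else ""
        complete = len(cds_seq) > 0 and len(cds_seq) % 3 == 0
        models[gid] = TranscriptModel(
            gene_id=gid,
            utr5=transcript_order(utr_ivs),
            cds=transcript_order(cds_ivs),
            utr5_seq=utr_seq,
            cds_seq=cds_seq,
            complete_cds=complete,
            starts_with_atg=cds_seq.startswith("ATG"),
        )
        if complete and not models[gid].starts_with_atg:
            log.warning("gene %s: complete CDS does not start with ATG", gid)
    return models


# ---------------------------------------------------------------------------
# 5'UTR source merging


def merge_utr_sources(sources: list[UtrAnnotationSource]) -> UtrAnnotationSource:
    """Combine several published 5'UTR annotation sets, keeping per gene the
    record with the greatest total 5'UTR length.

    Ties keep the record from the earliest source in the given order, which
    makes the merge idempotent and order-insensitive up to that tie-break.
    """
    merged: dict[str, list[GenomicInterval]] = {}
    best_len: dict[str, int] = {}
    for src in sources:
        for gid, ivs in src.records.items():
            if not ivs:
                raise ValueError(f"source {src.source_id}: gene {gid} has no intervals")
            total = sum(len(iv) for iv in ivs)
            if gid not in merged or total > best_len[gid]:
                merged[gid] = list(ivs)
                best_len[gid] = total
    return UtrAnnotationSource(source_id="merged", records=merged)


# ---------------------------------------------------------------------------
# export


def write_gff3(models: dict[str, TranscriptModel], path: str) -> None:
    """Write models back to GFF3 (CDS and five_prime_UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(models):
            m = models[gid]
            for ftype, ivs in (("five_prime_UTR", m.utr5), ("CDS", m.cds)):
                for iv in sorted(ivs, key=lambda iv: iv.start):
                    fh.write(
                        f"{iv.chrom}\triboshift\t{ftype}\t{iv.start + 1}\t{iv.end}"
                        f"\t.\t{iv.strand}\t.\tgene_id={gid}\n"
                    )


def gene_table(models: dict[str, TranscriptModel]) -> pd.DataFrame:
    """Per-gene summary: chrom, strand, 5'UTR and CDS lengths, flags."""
    rows = [
        {
            "gene_id": m.gene_id,
            "chrom": m.chrom,
            "strand": m.strand,
            "utr5_len": m.utr5_len,
            "cds_len": m.cds_len,
            "complete_cds": m.complete_cds,
            "starts_with_atg": m.starts_with_atg,
        }
        for m in models.values()
    ]
    return pd.DataFrame(rows).set_index("gene_id").sort_index()
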