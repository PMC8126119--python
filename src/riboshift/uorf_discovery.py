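"""AUG-initiated upstream ORF enumeration within 5'UTR sequences.

A uORF is any ATG..STOP stretch, in any frame, that starts and ends inside
the 5'UTR; overlapping and nested candidates are all reported and left to
downstream read-count filters.  ``n_codons`` counts start through stop codon
inclusive, so the default ``min_codons=10`` corresponds to peptides of at
least 9 amino acids.  Codons containing N never match ATG or a stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import (
    STOP_CODONS,
    GenomicInterval,
    TranscriptModel,
    transcript_order,
)


@dataclass
class UORFRecord:
    uorf_id: str
    gene_id: str
    tx_start: int  # offset of the A of ATG within utr5_seq
    tx_end: int  # exclusive offset just past the stop codon
    n_codons: int  # start through stop codon inclusive
    genomic_intervals: list[GenomicInterval] = field(default_factory=list)
    frame_anchor: int | None = None  # genomic coordinate of the A of ATG

    @property
    def peptide_len(self) -> int:
        return self.n_codons - 1

    def __post_init__(self) -> None:
        if self.tx_end - self.tx_start != 3 * self.n_codons:
            raise ValueError(
                f"{self.uorf_id}: span {self.tx_end - self.tx_start} != 3*{self.n_codons}"
            )


def scan_uorfs(
    utr5_seq: str, gene_id: str = "", min_codons: int = 10
) -> list[UORFRecord]:
    """Enumerate all ATG-to-stop ORFs of at least ``min_codons`` codons.

    Every ATG whose nearest in-frame stop lies fully within the sequence
    yields one candidate; ATGs with no in-frame stop inside the 5'UTR are
    dropped (such ORFs would run into the CDS).  Returns records in
    transcript coordinates, ordered by ``tx_start``.
    """
    seq = utr5_seq.upper()
    out: list[UORFRecord] = []
    ordinal = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                n_codons = (j + 3 - i) // 3
                if n_codons >= min_codons:
                    ordinal += 1
                    out.append(
                        UORFRecord(
                            uorf_id=f"{gene_id}.u{ordinal}" if gene_id else f"u{ordinal}",
                            gene_id=gene_id,
                            tx_start=i,
                            tx_end=j + 3,
                            n_codons=n_codons,
                        )
                    )
                break
    return out


def uorf_to_genomic(uorf: UORFRecord, model: TranscriptModel) -> UORFRecord:
    """Fill ``genomic_intervals`` by mapping transcript offsets through the
    5'UTR exon structure (splits across exon boundaries preserved)."""
    if uorf.tx_end > model.utr5_len:
        raise ValueError(
            f"{uorf.uorf_id}: tx_end {uorf.tx_end} past annotated 5'UTR "
            f"({model.utr5_len} nt)"
        )
    intervals: list[GenomicInterval] = []
    offset = 0  # transcript offset at the 5' edge of the current exon
    for iv in model.utr5:  # already in transcript order
        lo = max(uorf.tx_start, offset)
        hi = min(uorf.tx_end, offset + len(iv))
        if lo < hi:
            if iv.strand == "+":
                g0 = iv.start + (lo - offset)
                g1 = iv.start + (hi - offset)
            else:
                g1 = iv.end - (lo - offset)
                g0 = iv.end - (hi - offset)
            intervals.append(GenomicInterval(iv.chrom, g0, g1, iv.strand))
        offset += len(iv)
    intervals = transcript_order(intervals)
    first = intervals[0]
    anchor = first.start if first.strand == "+" else first.end - 1
    uorf.genomic_intervals = intervals
    uorf.frame_anchor = anchor
    return uorf


def discover_uorfs(
    models: dict[str, TranscriptModel], min_codons: int = 10
) -> list[UORFRecord]:
    """Scan every gene's 5'UTR and map all candidates to genomic coordinates."""
    out = []
    for gid in sorted(models):
        model = models[gid]
        if not model.utr5:
            continue
        for u in scan_uorfs(model.utr5_seq, gene_id=gid, min_codons=min_codons):
            out.append(uorf_to_genomic(u, model))
    return out


def write_uorf_bed(uorfs: list[UORFRecord], path: str) -> None:
    """BED-style TSV of uORFs in genomic coordinates (one block per exon)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tuorf_id\tn_codons\tstrand\tblocks\n")
        for u in uorfs:
            ivs = sorted(u.genomic_intervals, key=lambda iv: iv.start)
            blocks = ",".join(f"{iv.start}-{iv.end}" for iv in ivs)
            fh.write(
                f"{ivs[0].chrom}\t{ivs[0].start}\t{ivs[-1].end}\t{u.uorf_id}"
                f"\t{u.n_codons}\t{ivs[0].strand}\t{blocks}\n"
            )
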