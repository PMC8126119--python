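"""Read-to-feature assignment, P-site placement and per-uORF frame profiles.

Whole-read counting over CDS/5'UTR feature sets follows htseq-count
semantics: ``union`` assigns a read to the union of genes overlapping any
aligned base, ``intersection_strict`` to the intersection over every aligned
base of the genes covering that base (an uncovered base forces
``no_feature``).  The strict mode is used for 5'UTR counting to exclude
reads from ribosomes sitting on the first CDS codons.  Ribo-Seq P-sites are
placed by a per-read-length offset from the 5' end of the footprint, and
uORF occupancy is counted by P-site containment, split by reading frame
relative to the uORF's own ATG (f1 = in frame).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation_io import TranscriptModel
from .uorf_discovery import UORFRecord

#: default P-site offset per footprint length (5' end -> P-site, nt)
DEFAULT_PSITE_OFFSETS: dict[int, int] = {28: 12, 29: 12, 30: 12}


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-sample metadata.

    ``library_sizes`` holds total mapped reads per sample (assigned +
    ambiguous + no_feature), which is what CPM normalisation divides by.
    ``meta`` is indexed by sample_id with columns assay / condition /
    replicate.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        self.meta = self.meta.reindex(self.counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[sample_ids], self.library_sizes[sample_ids],
            self.meta.loc[sample_ids],
        )

    def select(self, **conditions) -> "CountMatrix":
        """Subset samples by metadata equality, e.g. ``select(assay='ribo')``."""
        mask = pd.Series(True, index=self.meta.index)
        for key, val in conditions.items():
            mask &= self.meta[key] == val
        return self.subset_samples(list(self.meta.index[mask]))


@dataclass
class FootprintProfile:
    """Per-codon in-frame P-site counts and frame totals for one uORF/sample."""

    uorf_id: str
    codon_counts: np.ndarray  # in-frame (f1) counts per codon position
    frame_counts: tuple[int, int, int]

    @property
    def n_reads(self) -> int:
        return int(sum(self.frame_counts))


# ---------------------------------------------------------------------------
# feature index and assignment


class FeatureIndex:
    """Interval index of one region set (CDS or 5'UTR) keyed by chrom/strand."""

    def __init__(self, models: dict[str, TranscriptModel], region: str):
        if region not in ("cds", "utr5"):
            raise ValueError(f"region must be 'cds' or 'utr5', got {region!r}")
        from .annotation_io import _merge_union

        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._gene_intervals: dict[str, list[tuple[int, int]]] = {}
        for m in models.values():
            # union-merge so per-gene coverage is well defined even when a
            # model carries overlapping intervals
            ivs = _merge_union(m.cds if region == "cds" else m.utr5)
            for iv in ivs:
                tree = self._trees.setdefault((iv.chrom, iv.strand), IntervalTree())
                tree.addi(iv.start, iv.end, m.gene_id)
                self._gene_intervals.setdefault(m.gene_id, []).append(
                    (iv.start, iv.end)
                )

    def overlapping(self, chrom: str, strand: str | None, start: int, end: int):
        """Gene ids with any feature base overlapping [start, end)."""
        strands = ("+", "-") if strand is None else (strand,)
        genes = set()
        for s in strands:
            tree = self._trees.get((chrom, s))
            if tree is not None:
                genes.update(hit.data for hit in tree.overlap(start, end))
        return genes

    def covered_length(self, gene_id: str, blocks: list[tuple[int, int]]) -> int:
        """Number of block bases covered by the gene's (merged) intervals."""
        total = 0
        for b0, b1 in blocks:
            for f0, f1 in self._gene_intervals.get(gene_id, ()):
                total += max(0, min(b1, f1) - max(b0, f0))
        return total


def assign_read(
    blocks: list[tuple[int, int]],
    chrom: str,
    strand: str | None,
    index: FeatureIndex,
    mode: str = "union",
) -> str:
    """Assign aligned blocks to a gene id, ``"ambiguous"`` or ``"no_feature"``.

    ``strand=None`` means unstranded counting (features on either strand
    match).  Gene feature intervals within one gene are union-merged at index
    construction, so per-gene coverage is well defined.
    """
    if mode not in ("union", "intersection_strict"):
        raise ValueError(f"unknown mode {mode!r}")
    candidates = set()
    for b0, b1 in blocks:
        candidates |= index.overlapping(chrom, strand, b0, b1)
    if mode == "union":
        genes = candidates
    else:
        read_len = sum(b1 - b0 for b0, b1 in blocks)
        genes = {
            g for g in candidates if index.covered_length(g, blocks) == read_len
        }
    if not genes:
        return "no_feature"
    if len(genes) > 1:
        return "ambiguous"
    return next(iter(genes))


# ---------------------------------------------------------------------------
# SAM counting


def count_features(
    sam_paths: dict[str, str],
    models: dict[str, TranscriptModel],
    region: str,
    mode: str,
    meta: pd.DataFrame,
    stranded: bool = True,
    min_mapq: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Count primary alignments per gene for each sample.

    Returns the :class:`CountMatrix` plus a per-sample accounting table with
    columns assigned / ambiguous / no_feature / low_mapq / total whose first
    three entries sum to the library size.
    """
    index = FeatureIndex(models, region)
    gene_ids = sorted(models)
    counts = pd.DataFrame(0, index=gene_ids, columns=list(sam_paths), dtype=np.int64)
    stats_rows = {}
    for sample_id, path in sam_paths.items():
        tallies = {"assigned": 0, "ambiguous": 0, "no_feature": 0, "low_mapq": 0}
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for rec in sam.fetch(until_eof=True):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    tallies["low_mapq"] += 1
                    continue
                blocks = rec.get_blocks()
                strand = ("-" if rec.is_reverse else "+") if stranded else None
                hit = assign_read(blocks, rec.reference_name, strand, index, mode)
                if hit == "no_feature":
                    tallies["no_feature"] += 1
                elif hit == "ambiguous":
                    tallies["ambiguous"] += 1
                else:
                    counts.loc[hit, sample_id] += 1
                    tallies["assigned"] += 1
        tallies["total"] = sum(tallies.values())
        stats_rows[sample_id] = tallies
    stats = pd.DataFrame(stats_rows).T
    lib = stats["assigned"] + stats["ambiguous"] + stats["no_feature"]
    return CountMatrix(counts, lib, meta), stats


# ---------------------------------------------------------------------------
# P-sites and uORF profiles


def psite_position(
    start: int, end: int, strand: str, read_length: int,
    offsets: dict[int, int] = DEFAULT_PSITE_OFFSETS,
) -> int | None:
    """Genomic coordinate of the P-site, or None if the length has no offset."""
    if read_length not in offsets:
        return None
    off = offsets[read_length]
    return start + off if strand == "+" else (end - 1) - off


def _tx_offset(pos: int, uorf: UORFRecord) -> int | None:
    """Transcript offset of a genomic P-site within the uORF (None if outside)."""
    off = 0
    for iv in uorf.genomic_intervals:  # transcript order
        if iv.start <= pos < iv.end:
            within = (pos - iv.start) if iv.strand == "+" else (iv.end - 1 - pos)
            return off + within
        off += len(iv)
    return None


def profile_uorf(psites: np.ndarray, uorf: UORFRecord) -> FootprintProfile:
    """Frame-resolved P-site profile of one uORF from genomic P-site coords.

    P-sites outside the uORF are ignored; frame is the transcript offset mod
    3 (0 = f1, the uORF's own reading frame), codon index is offset // 3.
    """
    n_codons = uorf.n_codons
    codon_counts = np.zeros(n_codons, dtype=np.int64)
    frames = [0, 0, 0]
    for pos in np.asarray(psites, dtype=np.int64):
        off = _tx_offset(int(pos), uorf)
        if off is None:
            continue
        frames[off % 3] += 1
        if off % 3 == 0:
            codon_counts[off // 3] += 1
    return FootprintProfile(uorf.uorf_id, codon_counts, tuple(frames))


def collect_psites(
    sam_path: str,
    offsets: dict[int, int] = DEFAULT_PSITE_OFFSETS,
    min_mapq: int = 0,
) -> dict[tuple[str, str], np.ndarray]:
    """All P-site coordinates of a sample, grouped by (chrom, strand).

    Reads whose length has no configured offset are skipped (tallied under
    the ``"__skipped__"`` key's length).
    """
    acc: dict[tuple[str, str], list[int]] = {}
    skipped = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            strand = "-" if rec.is_reverse else "+"
            pos = psite_position(
                rec.reference_start, rec.reference_end, strand,
                rec.query_length or rec.infer_read_length(), offsets,
            )
            if pos is None:
                skipped += 1
                continue
            acc.setdefault((rec.reference_name, strand), []).append(pos)
    out = {k: np.array(sorted(v), dtype=np.int64) for k, v in acc.items()}
    out[("__skipped__", ".")] = np.array([skipped], dtype=np.int64)
    return out


def uorf_count_table(
    sam_paths: dict[str, str],
    uorfs: list[UORFRecord],
    meta: pd.DataFrame,
    offsets: dict[int, int] = DEFAULT_PSITE_OFFSETS,
) -> tuple[pd.DataFrame, dict[tuple[str, str], FootprintProfile]]:
    """Per-uORF x sample P-site counts with f1/f2/f3 columns.

    Returns a long-format table (uorf_id, sample_id, f1, f2, f3, n_reads)
    and the underlying profiles keyed by (uorf_id, sample_id).
    """
    rows = []
    profiles: dict[tuple[str, str], FootprintProfile] = {}
    for sample_id, path in sam_paths.items():
        psites = collect_psites(path, offsets)
        for u in uorfs:
            key = (u.genomic_intervals[0].chrom, u.genomic_intervals[0].strand)
            prof = profile_uorf(psites.get(key, np.empty(0, dtype=np.int64)), u)
            profiles[(u.uorf_id, sample_id)] = prof
            f1, f2, f3 = prof.frame_counts
            rows.append(
                {
                    "uorf_id": u.uorf_id,
                    "gene_id": u.gene_id,
                    "sample_id": sample_id,
                    "f1": f1,
                    "f2": f2,
                    "f3": f3,
                    "n_reads": prof.n_reads,
                }
            )
    return pd.DataFrame(rows), profiles
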