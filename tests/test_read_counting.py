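import numpy as np
import pandas as pd
import pytest

from riboshift import annotation_io as ai
from riboshift import read_counting as rc
from riboshift import uorf_discovery as ud

from .oracles import per_base_assignment

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:c\tLN:10000\n"


def _models(features):
    """features: gene_id -> (region, [(start, end)], strand)."""
    models = {}
    for gid, (region, ivs, strand) in features.items():
        g_ivs = [ai.GenomicInterval("c", s, e, strand) for s, e in ivs]
        kwargs = {"utr5": ai.transcript_order(g_ivs)} if region == "utr5" else {
            "cds": ai.transcript_order(g_ivs)
        }
        models[gid] = ai.TranscriptModel(gene_id=gid, **kwargs)
    return models


class TestAssignRead:
    def setup_method(self):
        self.models = _models(
            {
                "gA": ("cds", [(100, 400)], "+"),
                "gB": ("cds", [(350, 700)], "+"),
            }
        )
        self.index = rc.FeatureIndex(self.models, "cds")

    def test_read_inside_one_gene_both_modes(self):
        for mode in ("union", "intersection_strict"):
            assert rc.assign_read([(150, 180)], "c", "+", self.index, mode) == "gA"

    def test_half_overlap_union_vs_strict(self):
        # half inside gA, half before any feature
        assert rc.assign_read([(80, 140)], "c", "+", self.index, "union") == "gA"
        assert (
            rc.assign_read([(80, 140)], "c", "+", self.index, "intersection_strict")
            == "no_feature"
        )

    def test_overlap_of_two_genes_is_ambiguous_in_union(self):
        assert rc.assign_read([(360, 390)], "c", "+", self.index, "union") == "ambiguous"

    def test_wrong_strand_is_no_feature_when_stranded(self):
        assert rc.assign_read([(150, 180)], "c", "-", self.index, "union") == "no_feature"
        assert rc.assign_read([(150, 180)], "c", None, self.index, "union") == "gA"

    def test_random_reads_match_per_base_oracle(self):
        rng = np.random.default_rng(20)
        n_checked = 0
        for _ in range(40):
            feats = {}
            for g in range(rng.integers(2, 6)):
                n_iv = int(rng.integers(1, 3))
                ivs = []
                for _ in range(n_iv):
                    s = int(rng.integers(0, 900))
                    ivs.append((s, s + int(rng.integers(10, 120))))
                feats[f"g{g}"] = ("cds", ivs, "+")
            models = _models(feats)
            index = rc.FeatureIndex(models, "cds")
            merged = {
                g: [(iv.start, iv.end) for iv in models[g].cds] for g in models
            }
            for _ in range(250):
                s = int(rng.integers(0, 950))
                blocks = [(s, s + int(rng.integers(1, 60)))]
                for mode in ("union", "intersection_strict"):
                    got = rc.assign_read(blocks, "c", "+", index, mode)
                    want = per_base_assignment(blocks, merged, mode)
                    assert got == want
                    n_checked += 1
        assert n_checked == 40 * 250 * 2


def _write_sam(path, rows):
    with open(path, "w") as fh:
        fh.write(SAM_HEADER)
        for i, (flag, pos, cigar, seq) in enumerate(rows):
            fh.write(f"r{i}\t{flag}\tc\t{pos}\t42\t{cigar}\t*\t0\t0\t{seq}\t*\n")


class TestCountFeatures:
    def test_library_size_includes_ambiguous(self, tmp_path):
        models = _models(
            {"gA": ("cds", [(100, 400)], "+"), "gB": ("cds", [(380, 700)], "+")}
        )
        sam = tmp_path / "s.sam"
        # 3 reads inside gA, 1 overlapping both genes (ambiguous)
        _write_sam(
            sam,
            [(0, 151, "30M", "A" * 30)] * 3 + [(0, 371, "30M", "A" * 30)],
        )
        meta = pd.DataFrame(
            {"assay": ["ribo"], "condition": ["normal"], "replicate": [1]},
            index=["s1"],
        )
        cm, stats = rc.count_features(
            {"s1": str(sam)}, models, "cds", "union", meta
        )
        assert cm.counts.loc["gA", "s1"] == 3
        assert cm.library_sizes["s1"] == 4
        assert stats.loc["s1", "ambiguous"] == 1

    def test_empty_sam_gives_zero_column(self, tmp_path):
        models = _models({"gA": ("cds", [(100, 400)], "+")})
        sam = tmp_path / "empty.sam"
        _write_sam(sam, [])
        meta = pd.DataFrame(
            {"assay": ["rna"], "condition": ["normal"], "replicate": [1]},
            index=["s1"],
        )
        cm, _ = rc.count_features({"s1": str(sam)}, models, "cds", "union", meta)
        assert cm.counts["s1"].sum() == 0
        assert cm.library_sizes["s1"] == 0

    def test_counts_equal_simulator_ledger(
        self, tiny_models, tiny_meta, tiny_sam_paths, tiny_ledger
    ):
        samples = [
            tiny_meta.index[tiny_meta.assay == "ribo"][0],
            tiny_meta.index[tiny_meta.assay == "rna"][0],
        ]
        paths = {s: tiny_sam_paths[s] for s in samples}
        for region, mode, led_region in (
            ("cds", "union", "cds"),
            ("utr5", "intersection_strict", "utr"),
        ):
            cm, stats = rc.count_features(
                paths, tiny_models, region, mode, tiny_meta.loc[samples]
            )
            for s in samples:
                led = (
                    tiny_ledger.query("sample_id == @s and region == @led_region")
                    .set_index("gene_id")["reads"]
                )
                assert (
                    cm.counts[s] == led.reindex(cm.counts.index).fillna(0)
                ).all()
                # conservation: tallies sum to total SAM records
                row = stats.loc[s]
                assert (
                    row["assigned"] + row["ambiguous"] + row["no_feature"]
                    + row["low_mapq"] == row["total"]
                )

    def test_strict_counts_never_exceed_union(
        self, tiny_models, tiny_meta, tiny_sam_paths
    ):
        s = tiny_meta.index[tiny_meta.assay == "ribo"][1]
        paths = {s: tiny_sam_paths[s]}
        union, _ = rc.count_features(
            paths, tiny_models, "utr5", "union", tiny_meta.loc[[s]]
        )
        strict, _ = rc.count_features(
            paths, tiny_models, "utr5", "intersection_strict", tiny_meta.loc[[s]]
        )
        assert (strict.counts[s] <= union.counts[s]).all()


class TestPsitePosition:
    @pytest.mark.parametrize(
        "start,end,strand,length,offset,expected",
        [
            (100, 129, "+", 29, 12, 112),
            (100, 129, "-", 29, 12, 116),
            (50, 51, "+", 1, 0, 50),
        ],
    )
    def test_offset_convention(self, start, end, strand, length, offset, expected):
        assert (
            rc.psite_position(start, end, strand, length, {length: offset})
            == expected
        )

    def test_unknown_length_returns_none(self):
        assert rc.psite_position(0, 33, "+", 33, {28: 12}) is None


class TestProfileUorf:
    def _uorf(self, strand="+"):
        u = ud.UORFRecord("u", "g", 0, 30, 10)
        iv = ai.GenomicInterval("c", 1000, 1030, strand)
        u.genomic_intervals = [iv]
        u.frame_anchor = 1000 if strand == "+" else 1029
        return u

    def test_perfect_periodicity(self):
        u = self._uorf()
        psites = np.array([1000 + 3 * k for k in range(10)])
        prof = rc.profile_uorf(psites, u)
        assert prof.frame_counts == (10, 0, 0)
        assert (prof.codon_counts == 1).all()
        assert prof.n_reads == 10

    def test_single_offframe_psite(self):
        u = self._uorf()
        prof = rc.profile_uorf(np.array([1000 + 3 * 3 + 1]), u)
        assert prof.frame_counts == (0, 1, 0)

    def test_psites_outside_uorf_ignored(self):
        u = self._uorf()
        prof = rc.profile_uorf(np.array([990, 1030, 5000]), u)
        assert prof.n_reads == 0

    def test_frame_assignment_mirrors_on_minus_strand(self):
        plus, minus = self._uorf("+"), self._uorf("-")
        # codon 2 first base: + offset 6 from 1000; - offset 6 from 1029
        p_plus = rc.profile_uorf(np.array([1006]), plus)
        p_minus = rc.profile_uorf(np.array([1023]), minus)
        assert p_plus.frame_counts == p_minus.frame_counts == (1, 0, 0)
        assert np.argmax(p_plus.codon_counts) == np.argmax(p_minus.codon_counts) == 2

    def test_planted_inframe_probability_recovered(
        self, tiny_uorfs, tiny_truth, tiny_meta, tiny_sam_paths
    ):
        ribo = tiny_meta[tiny_meta.assay == "ribo"]
        paths = {s: tiny_sam_paths[s] for s in ribo.index}
        table, profiles = rc.uorf_count_table(paths, tiny_uorfs, ribo)
        planted = [
            u.uorf_id
            for u in tiny_uorfs
            if tiny_truth.loc[u.gene_id, "has_uorf"]
            and u.tx_start == tiny_truth.loc[u.gene_id, "uorf_tx_start"]
        ]
        sub = table[table.uorf_id.isin(planted)]
        f1, n = sub.f1.sum(), sub.n_reads.sum()
        se = np.sqrt(0.85 * 0.15 / n)
        assert abs(f1 / n - 0.85) < 3 * se
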