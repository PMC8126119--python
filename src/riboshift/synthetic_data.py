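"""Synthetic stress-experiment generator with planted regulatory truth.

The generator emulates the statistical structure of paired Ribo-Seq/RNA-Seq
stress experiments in yeast:

* a global stress arrest of CDS translation — every gene's Ribo-Seq CDS
  density is multiplied by ``cds_arrest_tau`` (default 0.25) in stress,
  independently of uORFs (the "uORF-independent" mechanism); a
  ``uorf_dependent`` switch instead couples extra CDS repression to uORF
  up-translation, so the two mechanisms can be told apart downstream;
* stress-insensitive 5'UTR/uORF footprint density: upstream density tracks
  mRNA abundance but not the CDS arrest, so the 5'UTR:CDS ratio rises by
  ~1/tau in stress;
* gene classes regulated at transcription (RNA and footprints move
  together), translation (footprints only), or buffered (mRNA moves,
  footprints do not), with per-gene log2 effects drawn around
  ``effect_size``; translationally up-regulated genes carry uORFs whose
  stress translation drops (multiplier ``uorf_stress_rho``) in anti-phase
  with their CDS effect;
* negative-binomial count noise with gene-constant dispersion, and
* 3-nt periodic footprints: P-sites fall on the first base of a codon of
  the containing ORF with probability ``inframe_prob``.

Counts can be materialised alone (fast, any depth) or as full FASTA + GFF3 +
SAM files with an emission ledger (read-level, for small presets), and all
randomness flows from a single seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import revcomp
from .read_counting import CountMatrix

CLASSES = (
    "transcriptional_up",
    "transcriptional_down",
    "translational_up",
    "translational_down",
    "buffering_up",
    "buffering_down",
    "unchanged",
)

DEFAULT_PROPORTIONS = {
    "transcriptional_up": 0.10,
    "transcriptional_down": 0.10,
    "translational_up": 0.10,
    "translational_down": 0.10,
    "buffering_up": 0.10,
    "buffering_down": 0.10,
    "unchanged": 0.40,
}

#: class proportions echoing the observed 10-15% transcriptional and 6-12%
#: translational regulation in the real stress datasets
PAPERLIKE_PROPORTIONS = {
    "transcriptional_up": 0.065,
    "transcriptional_down": 0.060,
    "translational_up": 0.045,
    "translational_down": 0.045,
    "buffering_up": 0.025,
    "buffering_down": 0.025,
    "unchanged": 0.735,
}

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ["TAA", "TAG", "TGA"]

_UORF_MARGIN = 18  # nt clearance inside the 5'UTR so footprints stay within it
_SPACER = 100


@dataclass
class SimConfig:
    n_genes: int = 2000
    utr_len_range: tuple[int, int] = (60, 300)
    cds_len_codons_range: tuple[int, int] = (100, 500)
    uorf_prob: float = 0.5
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    effect_size: float = 2.0  # log2 units
    effect_size_sd: float = 0.35  # per-gene spread of the log2 effect
    cds_arrest_tau: float = 0.25
    uorf_stress_rho: float = 0.3
    scanning_factor: float = 0.1
    inframe_prob: float = 0.85
    nb_dispersion: float = 0.1
    depth: int = 5_000_000
    n_reps: int = 3
    read_len_probs: dict[int, float] = field(
        default_factory=lambda: {28: 0.3, 29: 0.4, 30: 0.3}
    )
    psite_offsets: dict[int, int] = field(
        default_factory=lambda: {28: 12, 29: 12, 30: 12}
    )
    uorf_dependent: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if not (1 / 3 < self.inframe_prob <= 1.0):
            raise ValueError("inframe_prob must be in (1/3, 1]")
        for key in ("cds_arrest_tau", "uorf_stress_rho", "scanning_factor"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be > 0")


@dataclass
class SimCounts:
    """Count-level simulation output: four count matrices plus gene truth."""

    config: SimConfig
    truth: pd.DataFrame  # per-gene class, multipliers, structure
    ribo_cds: CountMatrix
    ribo_utr: CountMatrix
    rna_cds: CountMatrix
    rna_utr: CountMatrix

    def matrix(self, assay: str, region: str) -> CountMatrix:
        return getattr(self, f"{assay}_{region}")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# gene-level truth


def _draw_truth(cfg: SimConfig) -> pd.DataFrame:
    rng = _rng(cfg.seed, 0)
    names = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in names])
    classes = rng.choice(names, size=cfg.n_genes, p=probs)
    lam = rng.lognormal(mean=3.0, sigma=1.0, size=cfg.n_genes)
    # class effects are exactly +/- effect_size; per-gene spread (delta) is
    # planted only in translational_up genes, where the uORF switch couples
    # anti-correlated uORF effects to the CDS effect
    eff = np.full(cfg.n_genes, cfg.effect_size)
    delta = rng.normal(0.0, cfg.effect_size_sd, size=cfg.n_genes)
    has_uorf = rng.random(cfg.n_genes) < cfg.uorf_prob
    utr_len = rng.integers(*cfg.utr_len_range, size=cfg.n_genes, endpoint=True)
    cds_codons = rng.integers(
        *cfg.cds_len_codons_range, size=cfg.n_genes, endpoint=True
    )

    a = np.zeros(cfg.n_genes)  # mRNA-abundance log2 change in stress
    b = np.zeros(cfg.n_genes)  # TE (ribosome-loading) log2 change in stress
    for i, cls in enumerate(classes):
        if cls == "transcriptional_up":
            a[i] = eff[i]
        elif cls == "transcriptional_down":
            a[i] = -eff[i]
        elif cls == "translational_up":
            b[i] = eff[i] + delta[i]
        elif cls == "translational_down":
            b[i] = -eff[i]
        elif cls == "buffering_up":
            a[i], b[i] = eff[i], -eff[i]
        elif cls == "buffering_down":
            a[i], b[i] = -eff[i], eff[i]

    # uORF stress behaviour: insensitive by default; anti-phase with the CDS
    # effect in translationally up-regulated genes (uORFs release in stress)
    u = np.zeros(cfg.n_genes)
    for i, cls in enumerate(classes):
        if not has_uorf[i]:
            continue
        if cls == "translational_up":
            # uORF translation drops in stress, in anti-phase with the
            # gene's realized CDS effect (stronger CDS activation <->
            # stronger uORF release)
            u[i] = np.log2(cfg.uorf_stress_rho) - (b[i] - cfg.effect_size)
        elif cfg.uorf_dependent:
            # uORF-dependent mechanism: uORF translation rises in stress and
            # the CDS is repressed proportionally on top of its class effect
            gain = np.abs(rng.normal(1.0, 0.3))
            u[i] = gain
            b[i] -= gain

    # place the planted uORF with clearance from the 5'UTR edges
    uorf_tx_start = np.full(cfg.n_genes, -1)
    uorf_codons = np.zeros(cfg.n_genes, dtype=np.int64)
    for i in range(cfg.n_genes):
        if not has_uorf[i]:
            continue
        max_codons = (int(utr_len[i]) - 2 * _UORF_MARGIN) // 3
        if max_codons < 10:
            # infeasible placement: widen the UTR rather than drop the uORF
            utr_len[i] = 10 * 3 + 2 * _UORF_MARGIN + 6
            max_codons = 10
        n_cod = int(rng.integers(10, min(20, max_codons), endpoint=True))
        uorf_codons[i] = n_cod
        hi = int(utr_len[i]) - _UORF_MARGIN - 3 * n_cod
        uorf_tx_start[i] = int(rng.integers(_UORF_MARGIN, hi, endpoint=True))

    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(cfg.n_genes)],
            "reg_class": classes,
            "lam": lam,
            "effect_log2": eff,
            "a_log2": a,
            "b_log2": b,
            "uorf_log2": u,
            "has_uorf": has_uorf,
            "utr_len": utr_len.astype(np.int64),
            "cds_codons": cds_codons.astype(np.int64),
            "uorf_tx_start": uorf_tx_start,
            "uorf_codons": uorf_codons,
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# count-level simulation


def _sample_plan(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for assay in ("ribo", "rna"):
        for cond in ("normal", "stress"):
            for rep in range(1, cfg.n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{assay}_{cond}_r{rep}",
                        "assay": assay,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _expected_means(cfg: SimConfig, truth: pd.DataFrame, assay: str, cond: str):
    """Unnormalised expected reads per gene for (cds, utr) regions."""
    lam = truth["lam"].to_numpy()
    a = 2.0 ** truth["a_log2"].to_numpy() if cond == "stress" else 1.0
    if assay == "rna":
        utr_frac = truth["utr_len"].to_numpy() / (
            truth["utr_len"].to_numpy() + 3.0 * truth["cds_codons"].to_numpy()
        )
        base = lam * a
        return base * (1 - utr_frac), base * utr_frac
    te = 2.0 ** truth["b_log2"].to_numpy() if cond == "stress" else 1.0
    tau = cfg.cds_arrest_tau if cond == "stress" else 1.0
    uorf = 2.0 ** truth["uorf_log2"].to_numpy() if cond == "stress" else 1.0
    cds = lam * a * te * tau
    utr = lam * a * cfg.scanning_factor * uorf
    return cds, utr


def simulate_counts(cfg: SimConfig) -> SimCounts:
    """Draw NB counts for all four feature tables under the planted truth."""
    truth = _draw_truth(cfg)
    meta = _sample_plan(cfg)
    depth_rng = _rng(cfg.seed, 1)
    tables: dict[str, dict[str, np.ndarray]] = {
        "ribo_cds": {}, "ribo_utr": {}, "rna_cds": {}, "rna_utr": {},
    }
    for s_idx, (sample_id, row) in enumerate(meta.iterrows()):
        cds_mean, utr_mean = _expected_means(cfg, truth, row["assay"], row["condition"])
        depth = cfg.depth * depth_rng.uniform(0.85, 1.15)
        scale = depth / (cds_mean.sum() + utr_mean.sum())
        rng = _rng(cfg.seed, 2, s_idx)
        counts = {}
        for region, mean in (("cds", cds_mean), ("utr", utr_mean)):
            m = mean * scale
            n = 1.0 / cfg.nb_dispersion
            counts[region] = rng.negative_binomial(n, n / (n + m))
        tables[f"{row['assay']}_cds"][sample_id] = counts["cds"]
        tables[f"{row['assay']}_utr"][sample_id] = counts["utr"]

    matrices = {}
    for assay in ("ribo", "rna"):
        sub_meta = meta[meta["assay"] == assay]
        sample_ids = list(sub_meta.index)
        cds_df = pd.DataFrame(tables[f"{assay}_cds"], index=truth.index)[sample_ids]
        utr_df = pd.DataFrame(tables[f"{assay}_utr"], index=truth.index)[sample_ids]
        lib = cds_df.sum(axis=0) + utr_df.sum(axis=0)
        matrices[f"{assay}_cds"] = CountMatrix(cds_df, lib, sub_meta)
        matrices[f"{assay}_utr"] = CountMatrix(utr_df, lib, sub_meta)
    return SimCounts(config=cfg, truth=truth, **matrices)


# ---------------------------------------------------------------------------
# sequence / read-level simulation


def _gene_sequences(cfg: SimConfig, truth: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """(utr5_seq, cds_seq) per gene with the planted uORF written in."""
    out = {}
    for g_idx, (gid, row) in enumerate(truth.iterrows()):
        rng = _rng(cfg.seed, 3, g_idx)
        utr = list(rng.choice(list("ACGT"), size=int(row["utr_len"])))
        if row["has_uorf"]:
            n_cod = int(row["uorf_codons"])
            body = ["ATG"] + [
                _NONSTOP_CODONS[i]
                for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_cod - 2)
            ] + [_STOPS[rng.integers(0, 3)]]
            s = int(row["uorf_tx_start"])
            utr[s : s + 3 * n_cod] = list("".join(body))
        cds = (
            "ATG"
            + "".join(
                _NONSTOP_CODONS[i]
                for i in rng.integers(
                    0, len(_NONSTOP_CODONS), size=int(row["cds_codons"]) - 2
                )
            )
            + _STOPS[rng.integers(0, 3)]
        )
        out[gid] = ("".join(utr), cds)
    return out


@dataclass
class _GeneLayout:
    chrom: str
    strand: str
    start: int  # genomic start of the transcript span (utr+cds)
    utr_iv: tuple[int, int]
    cds_iv: tuple[int, int]
    utr_len: int
    cds_len: int

    def tx_to_genomic(self, region: str, tx_off: int) -> int:
        """Genomic coordinate of a transcript offset within one region."""
        iv = self.utr_iv if region == "utr" else self.cds_iv
        if self.strand == "+":
            return iv[0] + tx_off
        return iv[1] - 1 - tx_off


def _layout_genome(
    cfg: SimConfig, truth: pd.DataFrame, seqs: dict[str, tuple[str, str]],
    genes_per_chrom: int = 50,
) -> tuple[dict[str, str], dict[str, _GeneLayout]]:
    chroms: dict[str, list[str]] = {}
    layouts: dict[str, _GeneLayout] = {}
    pos = 0
    chrom_parts: list[str] = []
    chrom_idx = 1

    def flush():
        nonlocal chrom_parts, pos, chrom_idx
        chroms[f"chrS{chrom_idx}"] = chrom_parts
        chrom_parts = []
        pos = 0
        chrom_idx += 1

    for g_idx, gid in enumerate(truth.index):
        utr, cds = seqs[gid]
        tx = utr + cds
        strand = "+" if g_idx % 2 == 0 else "-"
        chrom = f"chrS{chrom_idx}"
        chrom_parts.append("N" * _SPACER)
        start = pos + _SPACER
        if strand == "+":
            chrom_parts.append(tx)
            utr_iv = (start, start + len(utr))
            cds_iv = (start + len(utr), start + len(tx))
        else:
            chrom_parts.append(revcomp(tx))
            cds_iv = (start, start + len(cds))
            utr_iv = (start + len(cds), start + len(tx))
        pos = start + len(tx)
        layouts[gid] = _GeneLayout(
            chrom, strand, start, utr_iv, cds_iv, len(utr), len(cds)
        )
        if (g_idx + 1) % genes_per_chrom == 0:
            chrom_parts.append("N" * _SPACER)
            flush()
    if chrom_parts:
        chrom_parts.append("N" * _SPACER)
        flush()
    return {c: "".join(parts) for c, parts in chroms.items()}, layouts


def _emit_reads(
    cfg: SimConfig,
    rng: np.random.Generator,
    genome: dict[str, str],
    layout: _GeneLayout,
    row: pd.Series,
    region: str,
    assay: str,
    count: int,
    qname_prefix: str,
) -> list[str]:
    """SAM record lines for one gene/region/sample cell of the ledger."""
    lens = np.array(list(cfg.read_len_probs), dtype=np.int64)
    lprobs = np.array([cfg.read_len_probs[int(L)] for L in lens])
    lprobs = lprobs / lprobs.sum()
    read_lens = rng.choice(lens, size=count, p=lprobs)
    region_len = layout.utr_len if region == "utr" else layout.cds_len
    records = []
    for k in range(count):
        L = int(read_lens[k])
        if assay == "rna" or (region == "utr" and not row["has_uorf"]):
            # uniform placement fully inside the region
            tx0 = int(rng.integers(0, region_len - L, endpoint=True))
            if layout.strand == "+":
                start = layout.tx_to_genomic(region, tx0)
            else:
                start = layout.tx_to_genomic(region, tx0 + L - 1)
        else:
            off = cfg.psite_offsets[L]
            if region == "cds":
                n_cod = int(row["cds_codons"])
                orf_tx0 = 0
            else:
                n_cod = int(row["uorf_codons"])
                orf_tx0 = int(row["uorf_tx_start"])
            frame = 0 if rng.random() < cfg.inframe_prob else int(rng.integers(1, 3))
            codon = int(rng.integers(0, n_cod))
            psite_tx = orf_tx0 + 3 * codon + frame
            psite = layout.tx_to_genomic(region, psite_tx)
            if layout.strand == "+":
                start = psite - off
            else:
                start = psite + off + 1 - L
        end = start + L
        flag = 0 if layout.strand == "+" else 16
        seq = genome[layout.chrom][start:end]
        if layout.strand == "-":
            seq = revcomp(seq)
        records.append(
            f"{qname_prefix}.{k}\t{flag}\t{layout.chrom}\t{start + 1}\t42"
            f"\t{L}M\t*\t0\t0\t{seq}\t*"
        )
    return records


def simulate_experiment(cfg: SimConfig, out_dir: "str | Path") -> dict:
    """Write genome FASTA, GFF3, per-sample SAM files and truth tables.

    Counts come from :func:`simulate_counts` with the same seed, so the
    emission ledger equals the count tables and SAM line counts match the
    ledger by construction.  Returns a manifest dict (paths + checksums).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_counts(cfg)
    truth = sim.truth
    seqs = _gene_sequences(cfg, truth)
    genome, layouts = _layout_genome(cfg, truth, seqs)

    fasta_path = out / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    gff_path = out / "annotation.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, lay in layouts.items():
            for ftype, iv in (("five_prime_UTR", lay.utr_iv), ("CDS", lay.cds_iv)):
                fh.write(
                    f"{lay.chrom}\tribosim\t{ftype}\t{iv[0] + 1}\t{iv[1]}\t.\t"
                    f"{lay.strand}\t.\tgene_id={gid}\n"
                )

    header_lines = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{c}\tLN:{len(genome[c])}" for c in sorted(genome)
    ]
    sam_paths: dict[str, str] = {}
    ledger_rows = []
    all_meta = pd.concat([sim.ribo_cds.meta, sim.rna_cds.meta])
    for s_idx, (sample_id, srow) in enumerate(all_meta.iterrows()):
        assay = srow["assay"]
        cds_counts = sim.matrix(assay, "cds").counts[sample_id]
        utr_counts = sim.matrix(assay, "utr").counts[sample_id]
        path = out / f"{sample_id}.sam"
        with open(path, "w") as fh:
            fh.write("\n".join(header_lines) + "\n")
            for g_idx, gid in enumerate(truth.index):
                rng = _rng(cfg.seed, 4, s_idx, g_idx)
                for region, counts in (("cds", cds_counts), ("utr", utr_counts)):
                    c = int(counts.loc[gid])
                    if c == 0 and region == "utr":
                        ledger_rows.append(
                            {"sample_id": sample_id, "gene_id": gid,
                             "region": region, "reads": 0}
                        )
                        continue
                    recs = _emit_reads(
                        cfg, rng, genome, layouts[gid], truth.loc[gid],
                        region, assay, c, f"{sample_id}.{gid}.{region}",
                    )
                    for rec in recs:
                        fh.write(rec + "\n")
                    ledger_rows.append(
                        {"sample_id": sample_id, "gene_id": gid,
                         "region": region, "reads": c}
                    )
        sam_paths[sample_id] = str(path)

    truth_path = out / "truth_genes.tsv"
    truth.to_csv(truth_path, sep="\t")
    ledger = pd.DataFrame(ledger_rows)
    ledger_path = out / "truth_ledger.tsv"
    ledger.to_csv(ledger_path, sep="\t", index=False)
    meta_path = out / "samples.tsv"
    all_meta.to_csv(meta_path, sep="\t")

    files = [fasta_path, gff_path, truth_path, ledger_path, meta_path] + [
        Path(p) for p in sam_paths.values()
    ]
    manifest = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
        },
        "sam_paths": sam_paths,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# presets


PRESETS: dict[str, dict] = {
    "tiny": dict(n_genes=20, depth=20_000, n_reps=2, uorf_prob=0.7),
    "calibration": dict(n_genes=2000, depth=5_000_000, n_reps=3),
    "paperlike": dict(
        n_genes=2000, depth=5_000_000, n_reps=3,
        class_proportions=dict(PAPERLIKE_PROPORTIONS),
    ),
}

#: presets materialised at read level (SAM); larger presets stay count-level
_READ_LEVEL_PRESETS = {"tiny"}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)


def write_fixture(
    name: str, out_dir: "str | Path", seed: int = 0, force: bool = False
) -> dict:
    """Materialise a named preset on disk, deterministically for a seed.

    ``tiny`` writes the full read-level file set (FASTA/GFF3/SAM); the
    larger presets write count tables and truth only, since their contracts
    are count-statistical.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    cfg = preset_config(name, seed=seed)
    if name in _READ_LEVEL_PRESETS:
        return simulate_experiment(cfg, out)
    sim = simulate_counts(cfg)
    files = {}
    for key in ("ribo_cds", "ribo_utr", "rna_cds", "rna_utr"):
        path = out / f"counts_{key}.tsv"
        sim.matrix(*key.split("_")).counts.to_csv(path, sep="\t")
        files[path.name] = path
    truth_path = out / "truth_genes.tsv"
    sim.truth.to_csv(truth_path, sep="\t")
    files[truth_path.name] = truth_path
    meta_path = out / "samples.tsv"
    pd.concat([sim.ribo_cds.meta, sim.rna_cds.meta]).to_csv(meta_path, sep="\t")
    files[meta_path.name] = meta_path
    manifest = {
        "seed": seed,
        "preset": name,
        "files": {
            name_: hashlib.sha256(p.read_bytes()).hexdigest()
            for name_, p in files.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
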