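"""Class-wise uORF/5'UTR vs CDS density-change correlations and profiles.

For each regulatory class the question is whether stress-induced changes in
upstream (5'UTR or uORF) ribosome density track or oppose the changes in
CDS density.  The statistic is Spearman's rho over the class members'
(CDS log2FC, upstream log2FC) pairs; its significance against "any random
gene subset of the same size" comes from an empirical resampling null:
draw B random subsets of the full gene pool, recompute rho for each, and
report the +1-corrected tail probability, so B = 1000 gives a floor of
about 10^-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .annotation_io import TranscriptModel
from .uorf_discovery import UORFRecord


@dataclass
class ClassCorrelation:
    reg_class: str
    n_genes: int
    rho: float
    empirical_p: float | None
    n_draws: int
    seed: int | None


def class_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties; NaN below 3 finite pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        import warnings

        warnings.warn("class_correlation: fewer than 3 finite pairs")
        return float("nan")
    return float(st.spearmanr(x[ok], y[ok]).statistic)


def resampling_null(
    pool_x: np.ndarray,
    pool_y: np.ndarray,
    rho_obs: float,
    k: int,
    n_draws: int = 1000,
    seed: int = 0,
    alternative: str = "less",
) -> tuple[float, np.ndarray]:
    """Empirical p for an observed class rho against random k-subsets.

    Draws ``n_draws`` subsets of size k from the pool without replacement,
    computes rho for each, and returns ``(1 + #{null as or more extreme}) /
    (n_draws + 1)`` plus the null draws.  ``alternative='less'`` tests
    "more negative than chance" (null rho <= observed counts as extreme);
    ``'greater'`` the mirror image.
    """
    if alternative not in ("less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pool_x = np.asarray(pool_x, dtype=float)
    pool_y = np.asarray(pool_y, dtype=float)
    if k > pool_x.size:
        raise ValueError("subset size exceeds pool size")
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)
    for b in range(n_draws):
        idx = rng.choice(pool_x.size, size=k, replace=False)
        null[b] = class_correlation(pool_x[idx], pool_y[idx])
    if alternative == "less":
        extreme = int(np.sum(null <= rho_obs))
    else:
        extreme = int(np.sum(null >= rho_obs))
    return (1 + extreme) / (n_draws + 1), null


def class_correlations(
    changes: pd.DataFrame,
    classes: pd.Series,
    x_col: str = "cds_log2fc",
    y_col: str = "upstream_log2fc",
    n_draws: int = 1000,
    seed: int = 0,
    alternative: str = "less",
) -> pd.DataFrame:
    """Spearman rho and resampling empirical p per regulatory class.

    ``changes`` holds one row per gene with the CDS and upstream (5'UTR or
    uORF) Ribo-Seq log2FC columns; ``classes`` maps gene_id to reg_class.
    The null pool is the full set of genes with finite pairs.
    """
    merged = changes[[x_col, y_col]].copy()
    merged["reg_class"] = classes.reindex(merged.index)
    ok = np.isfinite(merged[x_col]) & np.isfinite(merged[y_col])
    merged = merged[ok]
    pool_x = merged[x_col].to_numpy()
    pool_y = merged[y_col].to_numpy()
    rows = []
    for i, (cls, sub) in enumerate(sorted(merged.groupby("reg_class"))):
        rho = class_correlation(sub[x_col].to_numpy(), sub[y_col].to_numpy())
        if np.isfinite(rho) and len(sub) < len(merged):
            emp_p, _ = resampling_null(
                pool_x, pool_y, rho, k=len(sub), n_draws=n_draws,
                seed=seed + i, alternative=alternative,
            )
        else:
            emp_p = np.nan
        rows.append(
            {
                "reg_class": cls,
                "n_genes": len(sub),
                "rho": rho,
                "empirical_p": emp_p,
                "n_draws": n_draws,
            }
        )
    pool_rho = class_correlation(pool_x, pool_y)
    rows.append(
        {
            "reg_class": "__pool__",
            "n_genes": len(merged),
            "rho": pool_rho,
            "empirical_p": np.nan,
            "n_draws": n_draws,
        }
    )
    return pd.DataFrame(rows).set_index("reg_class")


# ---------------------------------------------------------------------------
# per-gene footprint profile export


def gene_profile_export(
    gene_id: str,
    psites_by_condition: dict[str, dict[tuple[str, str], np.ndarray]],
    models: dict[str, TranscriptModel],
    uorfs: "list[UORFRecord] | None" = None,
) -> pd.DataFrame:
    """Per-base P-site coverage along one transcript (5'UTR + CDS), one
    column per condition with replicates pooled, uORF positions annotated.

    ``psites_by_condition`` maps condition -> {(chrom, strand): sorted
    P-site coordinates} (replicates already concatenated).
    """
    if gene_id not in models:
        raise KeyError(f"unknown gene {gene_id!r}")
    m = models[gene_id]
    # transcript position -> genomic coordinate, 5'UTR then CDS
    coords: list[int] = []
    regions: list[str] = []
    for label, ivs in (("utr5", m.utr5), ("cds", m.cds)):
        for iv in ivs:
            span = range(iv.start, iv.end) if iv.strand == "+" else range(
                iv.end - 1, iv.start - 1, -1
            )
            coords.extend(span)
            regions.extend([label] * len(iv))
    coords_arr = np.array(coords, dtype=np.int64)
    out = pd.DataFrame(
        {"tx_pos": np.arange(coords_arr.size), "genomic_pos": coords_arr,
         "region": regions}
    )
    key = (m.chrom, m.strand)
    for cond, psites in psites_by_condition.items():
        positions = psites.get(key, np.empty(0, dtype=np.int64))
        counts = pd.Series(positions).value_counts()
        out[f"count_{cond}"] = counts.reindex(coords_arr).fillna(0).to_numpy(
            dtype=np.int64
        )
    in_uorf = np.zeros(coords_arr.size, dtype=bool)
    if uorfs:
        spans = [
            (iv.start, iv.end)
            for u in uorfs
            if u.gene_id == gene_id
            for iv in u.genomic_intervals
        ]
        for s, e in spans:
            in_uorf |= (coords_arr >= s) & (coords_arr < e)
    out["in_uorf"] = in_uorf
    return out


def write_bedgraph(profile: pd.DataFrame, chrom: str, cond: str, path: str) -> None:
    """Write one condition's per-base coverage as a bedGraph track."""
    col = f"count_{cond}"
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{cond}"\n')
        for _, row in profile.sort_values("genomic_pos").iterrows():
            if row[col] > 0:
                g = int(row["genomic_pos"])
                fh.write(f"{chrom}\t{g}\t{g + 1}\t{int(row[col])}\n")
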