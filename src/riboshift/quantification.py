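"""CPM normalisation, fold changes, TE and 5'UTR:CDS density-shift summaries.

Conventions used throughout the stress/normal comparisons:

* CPM = 1e6 x count / library size (total mapped reads of the sample).
* Replicates are averaged on the CPM scale (arithmetic mean) before ratios.
* The minimum-coverage filter keeps a gene when its replicate-averaged raw
  count reaches 10 in at least one condition; only genes below 10 in *both*
  conditions are discarded.
* After filtering, zero cells receive a 0.5-read pseudocount before CPM so
  every log ratio stays finite; at the 10-read filter threshold the bias is
  negligible.
* The global 5'UTR:CDS shift sums raw counts over genes within each sample
  group: (sum UTR stress / sum CDS stress) / (sum UTR normal / sum CDS
  normal) — a depth-free composition statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .read_counting import CountMatrix

PSEUDOCOUNT = 0.5


def cpm(cm: CountMatrix, pseudocount: float = 0.0) -> pd.DataFrame:
    """Counts per million mapped reads; zero-library samples are dropped."""
    lib = cm.library_sizes.astype(float)
    keep = lib > 0
    if not keep.all():
        import warnings

        warnings.warn(f"dropping zero-library samples: {list(lib.index[~keep])}")
    counts = cm.counts.loc[:, keep.values].astype(float)
    if pseudocount:
        counts = counts.where(counts > 0, pseudocount)
    return 1e6 * counts / lib[keep]


def condition_means(
    table: pd.DataFrame, meta: pd.DataFrame, value_cols: "list[str] | None" = None
) -> pd.DataFrame:
    """Replicate-averaged values per condition (columns: normal, stress)."""
    cols = table.columns if value_cols is None else value_cols
    out = {}
    for cond in ("normal", "stress"):
        samples = [s for s in cols if meta.loc[s, "condition"] == cond]
        out[cond] = table[samples].mean(axis=1)
    return pd.DataFrame(out)


def filter_min_reads(cm: CountMatrix, min_mean: float = 10.0) -> pd.Index:
    """Genes kept by the coverage filter: replicate-averaged raw counts reach
    ``min_mean`` in at least one condition."""
    means = condition_means(cm.counts.astype(float), cm.meta)
    keep = (means["normal"] >= min_mean) | (means["stress"] >= min_mean)
    return cm.counts.index[keep.values]


def fold_change(cm: CountMatrix, min_mean: float = 10.0) -> pd.DataFrame:
    """Per-feature stress/normal fold change of replicate-averaged CPM.

    Applies the coverage filter, then the pseudocount policy, then averages
    CPM within condition.  Columns: cpm_normal, cpm_stress, fc, log2fc.
    """
    keep = filter_min_reads(cm, min_mean)
    sub = CountMatrix(cm.counts.loc[keep], cm.library_sizes, cm.meta)
    vals = cpm(sub, pseudocount=PSEUDOCOUNT)
    means = condition_means(vals, cm.meta)
    fc = means["stress"] / means["normal"]
    return pd.DataFrame(
        {
            "cpm_normal": means["normal"],
            "cpm_stress": means["stress"],
            "fc": fc,
            "log2fc": np.log2(fc),
        }
    )


def region_ratio_shift(
    utr_cm: CountMatrix,
    cds_cm: CountMatrix,
    scope: str = "per_gene",
    min_mean: float = 10.0,
) -> "pd.DataFrame | float":
    """Stress-vs-normal shift of the 5'UTR(or uORF):CDS ribosome-density ratio.

    ``per_gene`` returns one record per gene passing the coverage filter in
    both region tables, with ``log10_shift = log10(ratio_stress /
    ratio_normal)``.  ``global`` returns the scalar shift from summed raw
    counts over all genes (no per-gene filter), which is invariant to
    rescaling any sample's depth.
    """
    if scope == "global":
        shared = utr_cm.counts.index.intersection(cds_cm.counts.index)
        sums = {}
        for cond in ("normal", "stress"):
            usel = utr_cm.select(condition=cond).counts.loc[shared]
            csel = cds_cm.select(condition=cond).counts.loc[shared]
            sums[cond] = usel.values.sum() / csel.values.sum()
        return float(sums["stress"] / sums["normal"])
    if scope != "per_gene":
        raise ValueError(f"unknown scope {scope!r}")

    keep = filter_min_reads(utr_cm, min_mean).intersection(
        filter_min_reads(cds_cm, min_mean)
    )
    rows = []
    for region_cm in (utr_cm, cds_cm):
        sub = CountMatrix(region_cm.counts.loc[keep], region_cm.library_sizes,
                          region_cm.meta)
        vals = cpm(sub, pseudocount=PSEUDOCOUNT)
        rows.append(condition_means(vals, region_cm.meta))
    utr_means, cds_means = rows
    ratio_normal = utr_means["normal"] / cds_means["normal"]
    ratio_stress = utr_means["stress"] / cds_means["stress"]
    out = pd.DataFrame(
        {
            "ratio_normal": ratio_normal,
            "ratio_stress": ratio_stress,
            "log10_shift": np.log10(ratio_stress / ratio_normal),
        }
    )
    bad = ~np.isfinite(out["log10_shift"])
    if bad.any():
        import logging

        logging.getLogger(__name__).info(
            "dropping %d genes with undefined ratio shift", int(bad.sum())
        )
    return out[~bad]


def translational_efficiency(
    ribo_cm: CountMatrix,
    rna_cm: CountMatrix,
    region: str = "cds",
    min_mean: float = 10.0,
) -> pd.DataFrame:
    """TE = Ribo-Seq CPM / RNA-Seq CPM per condition, and its log2 change.

    Uses the dual-assay filter: a gene must pass the coverage filter in both
    the Ribo-Seq and the RNA-Seq table.
    """
    keep = filter_min_reads(ribo_cm, min_mean).intersection(
        filter_min_reads(rna_cm, min_mean)
    )
    means = []
    for cm_ in (ribo_cm, rna_cm):
        sub = CountMatrix(cm_.counts.loc[keep], cm_.library_sizes, cm_.meta)
        means.append(condition_means(cpm(sub, pseudocount=PSEUDOCOUNT), cm_.meta))
    ribo_means, rna_means = means
    te_normal = ribo_means["normal"] / rna_means["normal"]
    te_stress = ribo_means["stress"] / rna_means["stress"]
    return pd.DataFrame(
        {
            "region": region,
            "te_normal": te_normal,
            "te_stress": te_stress,
            "log2_te_change": np.log2(te_stress / te_normal),
        }
    )
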