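"""Differential expression on subsampled counts and regulatory classes.

The comparison of stress vs normal is run separately on RNA-Seq and
Ribo-Seq CDS counts, after (i) subsampling every sample to a common depth so
neither assay dominates statistical power, and (ii) TMM (trimmed mean of
M-values) normalisation to absorb composition shifts such as the global
translational arrest.  Per-gene testing is a voom-style moderated procedure:
log-CPM with a 0.5-count offset, a lowess mean-variance trend supplying
observation weights, a weighted two-group linear fit, and empirical-Bayes
shrinkage of residual variances toward a common prior before the moderated
t-test.  Benjamini-Hochberg controls FDR.  A gene counts as significantly
changed when its adjusted p-value is below alpha AND |log2FC| exceeds one
standard deviation of the assay's log2FC distribution.

Regulatory classes combine the two assays: significant in both with the
same sign = transcriptional change; Ribo-Seq only = translational change;
RNA-Seq only = post-transcriptional buffering; both but opposite signs =
discordant; neither = unchanged.

A secondary TE-change test fits, per gene, a negative-binomial GLM with log
link on counts from both assays and conditions (condition + assay +
condition:assay, offsets = log effective library size) and reads the
interaction term by likelihood ratio: a TE change is an assay-specific
condition effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .read_counting import CountMatrix

REG_CLASSES = (
    "transcriptional_up",
    "transcriptional_down",
    "translational_up",
    "translational_down",
    "buffering_up",
    "buffering_down",
    "discordant",
    "unchanged",
)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = sm.stats.multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# depth-equalizing subsampling


def subsample_counts(cm: CountMatrix, target_depth: int, seed: int) -> CountMatrix:
    """Draw exactly ``target_depth`` reads per sample without replacement.

    Each column becomes a multivariate-hypergeometric draw from its own
    counts, so column sums are exactly the target and gene composition is
    preserved in expectation.
    """
    rng = np.random.default_rng(seed)
    new = {}
    for sample_id in cm.sample_ids:
        col = cm.counts[sample_id].to_numpy()
        total = int(col.sum())
        if target_depth > total:
            raise ValueError(
                f"target depth {target_depth} exceeds sample {sample_id} "
                f"total {total}"
            )
        new[sample_id] = rng.multivariate_hypergeometric(col, target_depth)
    counts = pd.DataFrame(new, index=cm.counts.index)[cm.sample_ids]
    lib = pd.Series(target_depth, index=cm.sample_ids, dtype=np.int64)
    return CountMatrix(counts, lib, cm.meta)


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float, abs_trim: float,
) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / n_obs / obs + (n_ref - ref) / n_ref / ref
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = st.rankdata(log_r)
    rank_e = st.rankdata(abs_e)
    keep = (
        (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    )
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2**f)


def tmm_factors(
    counts: "pd.DataFrame | CountMatrix",
    lib_sizes: "pd.Series | None" = None,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalisation factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper-quartile; per sample the factor is the
    precision-weighted mean of gene-wise M-values after trimming the most
    extreme 30% of M-values and 5% of A-values, excluding genes with a zero
    in either column.  Matches the edgeR definition of TMM.
    """
    if isinstance(counts, CountMatrix):
        if lib_sizes is None:
            lib_sizes = counts.counts.sum(axis=0)
        counts = counts.counts
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = (
        counts.sum(axis=0).to_numpy(dtype=float)
        if lib_sizes is None
        else lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    )
    f75 = np.quantile(x, 0.75, axis=0) / lib
    if np.median(f75) < 1e-20:
        ref = int(np.argmax(np.sqrt(x).sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, i], x[:, ref], lib[i], lib[ref], logratio_trim, abs_trim)
            for i in range(x.shape[1])
        ]
    )
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("TMM failed: a sample shares no nonzero genes with the reference")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage (Smyth's moment estimator)


def _trigamma_inverse(x: float) -> float:
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink gene-wise variances toward a common prior.

    Fits a scaled F-distribution to the variances by moments on the log
    scale and returns (posterior variances, prior df, prior variance).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        # degenerate: (almost) no residual variation anywhere
        prior = float(s2[ok].mean()) if ok.any() else 1e-12
        return np.full_like(s2, prior), np.inf, prior
    z = np.log(np.where(ok, s2, 1.0))
    e = z - digamma(df / 2) + np.log(df / 2)
    e_mean = float(np.mean(e[ok]))
    n = int(ok.sum())
    e_var = float(np.sum((e[ok] - e_mean) ** 2) / (n - 1)) - float(polygamma(1, df / 2))
    if e_var > 0:
        df_prior = 2 * _trigamma_inverse(e_var)
        s2_prior = float(np.exp(e_mean + digamma(df_prior / 2) - np.log(df_prior / 2)))
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(e_mean))
        s2_post = np.full_like(s2, s2_prior)
    return s2_post, float(df_prior), s2_prior


# ---------------------------------------------------------------------------
# voom-style moderated two-group test


def _weighted_two_group(y, w, group):
    """Row-wise weighted LS fit of intercept + group; returns
    (logFC, unscaled SE of logFC, residual variance, fitted values)."""
    x1 = np.ones_like(group, dtype=float)
    x2 = group.astype(float)
    # normal-equation entries, per gene
    s11 = w @ (x1 * x1)
    s12 = w * x2[None, :] @ x1
    s22 = w @ (x2 * x2)
    t1 = (w * y) @ x1
    t2 = (w * y) @ x2
    det = s11 * s22 - s12**2
    b0 = (s22 * t1 - s12 * t2) / det
    b1 = (s11 * t2 - s12 * t1) / det
    fitted = b0[:, None] + b1[:, None] * x2[None, :]
    resid = y - fitted
    df = y.shape[1] - 2
    sigma2 = np.sum(w * resid**2, axis=1) / df
    se_unscaled = np.sqrt(s11 / det)  # [ (X'WX)^-1 ]_{22}
    return b1, se_unscaled, sigma2, fitted


def moderated_test(
    cm: CountMatrix,
    norm_factors: "pd.Series | None" = None,
    lowess_frac: float = 0.5,
) -> pd.DataFrame:
    """voom-style moderated t-test of stress vs normal on one assay.

    Returns per gene: log2fc_model, mean_logcpm, t, pvalue, adj_pvalue.
    Requires >= 2 replicates per condition.
    """
    cond = cm.meta["condition"]
    group = (cond == "stress").to_numpy()
    if (group.sum() < 2) or ((~group).sum() < 2):
        raise ValueError("moderated_test needs >= 2 replicates per condition")
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(cm.counts.columns).to_numpy(dtype=float)
    y = np.log2((counts + 0.5) / (lib + 1.0)[None, :] * 1e6)

    # first pass: unweighted fit for the mean-variance trend
    ones = np.ones_like(y)
    b1, _, sigma2, fitted = _weighted_two_group(y, ones, group)
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(np.sqrt(sigma2))  # sqrt of residual SD
    smoothed = lowess(sy, sx, frac=lowess_frac, return_sorted=True)
    trend_x, trend_y = smoothed[:, 0], smoothed[:, 1]

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    # floor the trend so exactly-replicated fixtures keep finite weights
    trend_pred = np.maximum(np.interp(fitted_logcount, trend_x, trend_y), 1e-6)
    w = 1.0 / trend_pred**4

    b1, se_unscaled, sigma2, _ = _weighted_two_group(y, w, group)
    df_resid = y.shape[1] - 2
    s2_post, df_prior, _ = squeeze_var(sigma2, df_resid)
    tstat = b1 / (se_unscaled * np.sqrt(s2_post))
    df_total = df_resid + df_prior
    if np.isfinite(df_total):
        pvals = 2 * st.t.sf(np.abs(tstat), df_total)
    else:
        pvals = 2 * st.norm.sf(np.abs(tstat))
    return pd.DataFrame(
        {
            "log2fc_model": b1,
            "mean_logcpm": y.mean(axis=1),
            "t": tstat,
            "pvalue": pvals,
            "adj_pvalue": bh_adjust(pvals),
        },
        index=cm.counts.index,
    )


def sd_threshold(dge: pd.DataFrame) -> float:
    """One standard deviation of the assay's model log2FC distribution."""
    vals = dge["log2fc_model"].to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError("sd_threshold needs >= 2 genes")
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# regulatory classes


def _flag(dge: pd.DataFrame, alpha: float, thr: float) -> pd.DataFrame:
    sig = (dge["adj_pvalue"] < alpha) & (dge["log2fc_model"].abs() > thr)
    return pd.DataFrame(
        {"significant": sig, "sign": np.sign(dge["log2fc_model"])}, index=dge.index
    )


def classify_regulation(
    rna: pd.DataFrame,
    ribo: pd.DataFrame,
    alpha: float = 0.05,
    rna_sd: "float | None" = None,
    ribo_sd: "float | None" = None,
) -> pd.DataFrame:
    """Assign each gene a regulatory class from the two assays' results.

    Classes: transcriptional_{up,down} (both significant, concordant),
    translational_{up,down} (Ribo-Seq only, by Ribo-Seq sign),
    buffering_{up,down} (RNA-Seq only, by RNA-Seq sign), discordant (both
    significant, opposite signs), unchanged.  Genes missing from one assay
    are unchanged with ``tested_both=False``.
    """
    rna_sd = sd_threshold(rna) if rna_sd is None else rna_sd
    ribo_sd = sd_threshold(ribo) if ribo_sd is None else ribo_sd
    rna_f = _flag(rna, alpha, rna_sd)
    ribo_f = _flag(ribo, alpha, ribo_sd)
    genes = rna.index.union(ribo.index)
    rows = []
    for g in genes:
        in_both = g in rna_f.index and g in ribo_f.index
        if not in_both:
            rows.append({"gene_id": g, "reg_class": "unchanged", "tested_both": False})
            continue
        r_sig, r_sign = bool(rna_f.loc[g, "significant"]), rna_f.loc[g, "sign"]
        b_sig, b_sign = bool(ribo_f.loc[g, "significant"]), ribo_f.loc[g, "sign"]
        if r_sig and b_sig:
            cls = (
                ("transcriptional_up" if b_sign > 0 else "transcriptional_down")
                if r_sign == b_sign
                else "discordant"
            )
        elif b_sig:
            cls = "translational_up" if b_sign > 0 else "translational_down"
        elif r_sig:
            cls = "buffering_up" if r_sign > 0 else "buffering_down"
        else:
            cls = "unchanged"
        rows.append({"gene_id": g, "reg_class": cls, "tested_both": True})
    out = pd.DataFrame(rows).set_index("gene_id")
    out["rna_log2fc"] = rna["log2fc_model"].reindex(out.index)
    out["ribo_log2fc"] = ribo["log2fc_model"].reindex(out.index)
    out["rna_adj_pvalue"] = rna["adj_pvalue"].reindex(out.index)
    out["ribo_adj_pvalue"] = ribo["adj_pvalue"].reindex(out.index)
    return out


# ---------------------------------------------------------------------------
# TE-change interaction test


def te_change_test(
    rna_cm: CountMatrix,
    ribo_cm: CountMatrix,
    alpha: float = 0.05,
    min_dispersion: float = 1e-4,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Per-gene NB-GLM likelihood-ratio test of the condition:assay interaction.

    Counts from both assays are modelled jointly with log effective library
    sizes as offsets; the interaction term is the TE change on the natural
    log scale (reported as log2).  Gene-wise dispersion is a Pearson
    method-of-moments estimate under the full model; because a per-gene
    estimate from n - p residual degrees of freedom is noisy enough to make
    the plug-in chi-square LRT anticonservative, each gene's dispersion is
    shrunk toward the experiment-wide median with ``prior_df`` residual
    degrees of freedom of weight, then floored at ``min_dispersion``.
    All-zero genes are reported NA.
    """
    genes = rna_cm.counts.index.intersection(ribo_cm.counts.index)
    mats, conds, assays, offs = [], [], [], []
    for assay_val, cm_ in ((0.0, rna_cm), (1.0, ribo_cm)):
        eff_lib = cm_.counts.sum(axis=0).to_numpy(dtype=float) * tmm_factors(
            cm_.counts
        ).to_numpy(dtype=float)
        mats.append(cm_.counts.loc[genes].to_numpy(dtype=float))
        conds.append((cm_.meta["condition"] == "stress").to_numpy(dtype=float))
        assays.append(np.full(cm_.counts.shape[1], assay_val))
        offs.append(np.log(eff_lib))
    y_all = np.hstack(mats)
    cond = np.concatenate(conds)
    assay = np.concatenate(assays)
    offset = np.concatenate(offs)
    x_full = np.column_stack([np.ones_like(cond), cond, assay, cond * assay])
    x_red = x_full[:, :3]

    n, p = y_all.shape[1], x_full.shape[1]
    df_resid = n - p
    # pass 1: gene-wise Pearson method-of-moments dispersions
    raw_disp = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        yv = y_all[i]
        if yv.sum() == 0:
            continue
        try:
            mu = sm.GLM(
                yv, x_full, family=sm.families.Poisson(), offset=offset
            ).fit().mu
            raw_disp[i] = np.sum((yv - mu) ** 2 / mu**2 - 1.0 / mu) / df_resid
        except Exception:
            pass
    finite = raw_disp[np.isfinite(raw_disp)]
    prior = float(np.median(finite)) if finite.size else min_dispersion

    rows = []
    for i, g in enumerate(genes):
        yv = y_all[i]
        if yv.sum() == 0 or not np.isfinite(raw_disp[i]):
            rows.append({"gene_id": g, "interaction_log2": np.nan,
                         "lrt_stat": np.nan, "pvalue": np.nan})
            continue
        disp = (df_resid * raw_disp[i] + prior_df * prior) / (df_resid + prior_df)
        disp = max(min_dispersion, disp)
        try:
            fam = sm.families.NegativeBinomial(alpha=disp)
            full = sm.GLM(yv, x_full, family=fam, offset=offset).fit()
            red = sm.GLM(yv, x_red, family=fam, offset=offset).fit()
            lrt = max(0.0, 2.0 * (full.llf - red.llf))
            pval = st.chi2.sf(lrt, df=1)
            est = full.params[3] / np.log(2)
        except Exception:
            est, lrt, pval = np.nan, np.nan, np.nan
        rows.append({"gene_id": g, "interaction_log2": est,
                     "lrt_stat": lrt, "pvalue": pval})
    out = pd.DataFrame(rows).set_index("gene_id")
    out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["adj_pvalue"] < alpha
    return out
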