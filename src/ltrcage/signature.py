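"""Tumor signature selection, sample stratification, and clinical association.

Signature peaks are distal peaks passing three stringent criteria (FDR below
1e-10, fold change strictly above 8, expression — at least one tag — in at
least 30 tumor samples), named PREFIX-001... in ascending FDR order. Samples
are stratified by agglomerative (UPGMA, Euclidean) clustering of
log10(tpm + 0.005) signature profiles cut into k = 3 groups labeled
high/intermediate/low by mean signature expression; associations of the high
vs low strata with binary clinical covariates use Fisher tests, Woolf CIs
and Cochran's Q heterogeneity across the covariate log odds ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .stats import ContingencyTable, bh_fdr, cochran_q

logger = logging.getLogger(__name__)


def select_signature(diff: pd.DataFrame, counts: pd.DataFrame,
                     distal_ids, tumor_samples, ltr_flags: pd.Series,
                     fdr_max: float = 1e-10, fold_min: float = 8.0,
                     min_tumor_samples: int = 30,
                     prefix: str = "LTR") -> pd.DataFrame:
    """Distal peaks passing all three signature criteria, FDR-ascending.

    ``fold_min`` is a strict inequality on the linear fold change;
    "expressed" means >= 1 tag in the tumor sample. An empty signature is
    allowed (logged). ``ltr_flags`` is a boolean Series over peak ids.
    """
    tumor_samples = list(tumor_samples)
    ids = [i for i in distal_ids if i in diff.index]
    sub = diff.loc[ids]
    n_expr = (counts.loc[ids, tumor_samples] >= 1).sum(axis=1)
    fold = np.exp2(sub["log2_fold"])
    keep = ((sub["fdr_bh"] < fdr_max) & (fold > fold_min)
            & (n_expr >= min_tumor_samples))
    sel = sub[keep]
    # FDR-ascending order; peak-id tiebreak keeps output input-order independent
    order = sorted(sel.index, key=lambda pid: (sel.at[pid, "fdr_bh"],
                                               sel.at[pid, "p_exact"], pid))
    out = pd.DataFrame({
        "fdr_bh": sel["fdr_bh"].reindex(order),
        "fold_change": fold.reindex(order),
        "n_tumor_expressed": n_expr.reindex(order),
        "ltr_flag": ltr_flags.reindex(order).fillna(False).astype(bool),
    })
    out.insert(0, "name", [f"{prefix}-{i + 1:03d}" for i in range(len(out))])
    if out.empty:
        logger.info("signature selection produced an empty set")
    return out


def atlas_breadth(signature_ids, atlas: pd.DataFrame, tumor: pd.DataFrame,
                  mode: str = "above tumor median") -> dict:
    """Atlas breadth of the signature: counts above the tumor-median threshold.

    The per-peak threshold is the median expression across tumor samples; an
    atlas sample "expresses" a peak when its value is strictly greater.
    Peaks missing from the atlas count as unexpressed (tallied). Returns
    per-peak atlas counts, per-atlas-sample signature counts (ranked), and
    the missing-peak tally.
    """
    ids = list(signature_ids)
    thresholds = tumor.loc[tumor.index.intersection(ids)].median(axis=1)
    missing = [i for i in ids if i not in atlas.index]
    present = [i for i in ids if i in atlas.index]
    sub = atlas.loc[present]
    if mode == "above tumor median":
        expressed = sub.gt(thresholds.reindex(present), axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    per_peak = expressed.sum(axis=1).reindex(ids).fillna(0).astype(int)
    per_sample = expressed.sum(axis=0).sort_values(ascending=False)
    return {"per_peak": per_peak, "per_sample": per_sample,
            "missing_peaks": len(missing)}


def cluster_samples(tpm: pd.DataFrame, signature_ids, k: int = 3,
                    log_pseudocount: float = 0.005,
                    log_transform: bool = True) -> dict:
    """UPGMA stratification of samples on signature expression.

    Clusters sample vectors of log10(tpm + pseudocount) over the signature
    peaks with average linkage and Euclidean distance, cuts the tree into
    exactly ``k`` groups, and labels strata high/intermediate/low by
    descending mean signature expression. Returns assignment Series,
    linkage matrix, and per-stratum means.
    """
    ids = [i for i in signature_ids if i in tpm.index]
    if not ids:
        raise ValueError("empty signature")
    X = tpm.loc[ids].T  # samples x peaks
    if k > len(X):
        raise ValueError(f"k={k} exceeds {len(X)} samples")
    if log_transform:
        X = np.log10(X + log_pseudocount)
    Z = hierarchy.linkage(X.to_numpy(), method="average", metric="euclidean")
    flat = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    means = pd.Series(X.to_numpy().mean(axis=1), index=X.index)
    order = (means.groupby(flat).mean().sort_values(ascending=False).index
             .tolist())
    names = ["high", "intermediate", "low"] if k == 3 else [
        f"stratum_{i + 1}" for i in range(k)]
    mapping = {cl: names[i] for i, cl in enumerate(order)}
    strata = pd.Series([mapping[c] for c in flat], index=X.index,
                       name="stratum")
    return {"strata": strata, "linkage": Z,
            "stratum_means": means.groupby(strata).mean()}


def pca_embed(tpm: pd.DataFrame, signature_ids,
              log_pseudocount: float = 0.005) -> dict:
    """2-D PCA of samples on centered log-scaled signature expression.

    Deterministic sign convention: within each component the
    largest-magnitude loading is made positive.
    """
    ids = [i for i in signature_ids if i in tpm.index]
    if not ids:
        raise ValueError("empty signature")
    X = np.log10(tpm.loc[ids].T + log_pseudocount)
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for comp in range(min(2, Vt.shape[0])):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    coords = U[:, :2] * S[:2]
    var = S ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    return {"coords": pd.DataFrame(coords, index=X.index,
                                   columns=["PC1", "PC2"]),
            "explained_variance_ratio": explained[:2],
            "loadings": pd.DataFrame(Vt[:2].T, index=ids,
                                     columns=["PC1", "PC2"])}


def clinical_association(strata: pd.Series, sheet: pd.DataFrame,
                         covariates) -> dict:
    """High-vs-low stratum association with binary clinical covariates.

    Per covariate: 2x2 (stratum x level) with Fisher two-sided p, Woolf 95%
    CI (Haldane-Anscombe corrected when needed), BH FDR across covariates,
    plus Cochran's Q heterogeneity across the covariate log odds ratios.
    Intermediate-stratum samples are excluded; one-level covariates are
    skipped with a tally.
    """
    high = strata.index[strata == "high"]
    low = strata.index[strata == "low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("need >= 2 samples in each of the high/low strata")
    rows, skipped = [], []
    log_ors, ses = [], []
    for cov in covariates:
        vals = sheet[cov]
        hi_vals = vals.reindex(high).dropna().astype(int)
        lo_vals = vals.reindex(low).dropna().astype(int)
        levels = set(hi_vals) | set(lo_vals)
        if len(levels) < 2:
            skipped.append(cov)
            continue
        a = int((hi_vals == 1).sum())
        b = int((hi_vals == 0).sum())
        c = int((lo_vals == 1).sum())
        d = int((lo_vals == 0).sum())
        t = ContingencyTable(a, b, c, d)
        lo_ci, hi_ci = t.ci95()
        lor, se = t.log_or_se()
        log_ors.append(lor)
        ses.append(se)
        rows.append((cov, a, b, c, d, t.odds_ratio, lo_ci, hi_ci,
                     t.fisher_p("two-sided")))
    table = pd.DataFrame(rows, columns=[
        "covariate", "high_pos", "high_neg", "low_pos", "low_neg",
        "odds_ratio", "ci95_low", "ci95_high", "p_fisher"])
    table["fdr_bh"] = bh_fdr(table["p_fisher"].to_numpy())
    q, q_p = cochran_q(log_ors, ses) if len(log_ors) >= 2 else (np.nan, np.nan)
    return {"table": table, "heterogeneity_q": q, "heterogeneity_p": q_p,
            "skipped": skipped}


def forest_plot(association_table: pd.DataFrame, path) -> None:
    """Write a forest plot of covariate odds ratios with 95% CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = association_table
    fig, ax = plt.subplots(figsize=(6, 0.5 * max(len(df), 2) + 1.5))
    y = np.arange(len(df))[::-1]
    ax.errorbar(df["odds_ratio"], y,
                xerr=[df["odds_ratio"] - df["ci95_low"],
                      df["ci95_high"] - df["odds_ratio"]],
                fmt="s", color="k", capsize=3)
    ax.axvline(1.0, color="grey", linestyle="--")
    ax.set_yticks(y)
    ax.set_yticklabels(df["covariate"])
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (high vs low stratum)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
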