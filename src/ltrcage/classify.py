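"""Coding / proximal / distal taxonomy of CAGE peaks and Fig-1-style summaries.

The cascade: a peak is *coding* if its interval intersects a protein-coding
TSS window (TSS +/- 100 bp, inclusive) in sense orientation; otherwise
*proximal* if its summit lies within 5 kb of a coding peak's summit (any
strand) or its interval intersects a coding exon (either strand); otherwise
*distal*. Distances are summit-to-summit on the same chromosome; ties go to
the smaller coordinate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .clustering import count_tags_in_peaks

LABELS = ("coding", "proximal", "distal")


def _interval_trees(items) -> dict:
    trees: dict = {}
    for key, start, end, payload in items:
        trees.setdefault(key, IntervalTree()).addi(start, end, payload)
    return trees


def classify_peaks(peaks: pd.DataFrame, genes: list,
                   coding_window_bp: int = 100,
                   proximal_bp: int = 5000) -> pd.DataFrame:
    """Assign each peak a {coding, proximal, distal} label.

    Returns a frame indexed like ``peaks`` with columns label,
    closest_coding_peak, distance (summit-to-summit bp, NaN when no coding
    peak shares the chromosome) and same_strand.
    """
    coding_genes = [g for g in genes if g.biotype == "protein_coding"]
    tss_items = [((g.chrom, g.strand), g.tss_pos - coding_window_bp,
                  g.tss_pos + coding_window_bp + 1, g.gene_id)
                 for g in coding_genes]
    tss_trees = _interval_trees(tss_items)
    exon_items = [(g.chrom, s, e, g.gene_id)
                  for g in coding_genes for s, e in g.exons]
    exon_trees = _interval_trees(exon_items)

    is_coding = np.zeros(len(peaks), dtype=bool)
    for i, row in enumerate(peaks.itertuples(index=False)):
        tree = tss_trees.get((row.chrom, row.strand))
        if tree is not None and tree.overlap(row.start, row.end):
            is_coding[i] = True

    coding_idx = np.flatnonzero(is_coding)
    coding_peaks = peaks.iloc[coding_idx]
    coding_by_chrom = {
        chrom: (grp["summit"].to_numpy(), grp["peak_id"].to_numpy(),
                grp["strand"].to_numpy())
        for chrom, grp in coding_peaks.groupby("chrom")
    }
    # sort summits per chromosome for nearest-neighbour queries
    for chrom, (summits, ids, strands) in coding_by_chrom.items():
        order = np.argsort(summits, kind="mergesort")
        coding_by_chrom[chrom] = (summits[order], ids[order], strands[order])

    labels, closest, dists, same_strand = [], [], [], []
    for i, row in enumerate(peaks.itertuples(index=False)):
        near_id, near_dist, near_same = None, np.nan, False
        entry = coding_by_chrom.get(row.chrom)
        if entry is not None and len(entry[0]):
            summits, ids, strands = entry
            j = int(np.searchsorted(summits, row.summit))
            cand = [k for k in (j - 1, j) if 0 <= k < len(summits)]
            # ties broken toward the smaller coordinate
            best = min(cand, key=lambda k: (abs(int(summits[k]) - row.summit),
                                            summits[k]))
            near_id = ids[best]
            near_dist = abs(int(summits[best]) - row.summit)
            near_same = strands[best] == row.strand
        closest.append(near_id)
        dists.append(near_dist)
        same_strand.append(near_same)
        if is_coding[i]:
            labels.append("coding")
            continue
        prox = (near_id is not None and near_dist <= proximal_bp)
        if not prox:
            tree = exon_trees.get(row.chrom)
            prox = tree is not None and bool(tree.overlap(row.start, row.end))
        labels.append("proximal" if prox else "distal")

    return pd.DataFrame({
        "label": pd.Categorical(labels, categories=list(LABELS)),
        "closest_coding_peak": closest,
        "distance": dists,
        "same_strand": same_strand,
    }, index=peaks["peak_id"])


def distance_spectrum(classified: pd.DataFrame, peaks: pd.DataFrame,
                      expressed_coding_ids, far_bp: int = 100_000) -> dict:
    """Distances from distal peaks to the nearest *expressed* coding peak.

    Returns per-peak distances, a log10-binned histogram, the fraction of
    distal peaks beyond ``far_bp`` and the tally of peaks with no expressed
    coding peak on their chromosome (excluded from the histogram).
    """
    expressed_coding_ids = set(expressed_coding_ids)
    if not expressed_coding_ids:
        raise ValueError("no expressed coding peaks")
    pk = peaks.set_index("peak_id")
    coding = pk.loc[pk.index.isin(expressed_coding_ids)]
    by_chrom = {}
    for chrom, grp in coding.groupby("chrom"):
        summits = np.sort(grp["summit"].to_numpy())
        by_chrom[chrom] = summits
    distal_ids = classified.index[classified["label"] == "distal"]
    dists = {}
    unreachable = 0
    for pid in distal_ids:
        row = pk.loc[pid]
        summits = by_chrom.get(row["chrom"])
        if summits is None or not len(summits):
            unreachable += 1
            continue
        j = int(np.searchsorted(summits, row["summit"]))
        cand = [k for k in (j - 1, j) if 0 <= k < len(summits)]
        best = min(cand, key=lambda k: (abs(int(summits[k]) - row["summit"]),
                                        summits[k]))
        dists[pid] = abs(int(summits[best]) - int(row["summit"]))
    d = pd.Series(dists, dtype=float)
    log_edges = np.arange(0, 8.5, 0.5)
    hist, _ = np.histogram(np.log10(np.maximum(d.to_numpy(), 1.0)),
                           bins=log_edges)
    frac_far = float((d > far_bp).mean()) if len(d) else float("nan")
    return {"distances": d, "hist": hist, "log_edges": log_edges,
            "fraction_far": frac_far, "unreachable": unreachable}


def bidirectionality_profile(classified: pd.DataFrame, peaks: pd.DataFrame,
                             window_bp: int = 5000,
                             bin_bp: int = 100) -> pd.DataFrame:
    """Orientation-aware offsets of proximal peaks around coding summits.

    Offset = proximal summit - coding summit, sign flipped for minus-strand
    coding genes so that negative means upstream of the coding TSS. Returns a
    per-peak frame (offset, same_strand) limited to |offset| <= window_bp.
    """
    pk = peaks.set_index("peak_id")
    coding_strand = pk["strand"]
    rows = []
    prox = classified[classified["label"] == "proximal"]
    for pid, row in prox.iterrows():
        cid = row["closest_coding_peak"]
        if cid is None or (isinstance(cid, float) and np.isnan(cid)):
            continue
        offset = int(pk.at[pid, "summit"]) - int(pk.at[cid, "summit"])
        if coding_strand[cid] == "-":
            offset = -offset
        if abs(offset) <= window_bp:
            rows.append((pid, offset, bool(row["same_strand"])))
    return pd.DataFrame(rows, columns=["peak_id", "offset", "same_strand"]
                        ).set_index("peak_id")


def neighbor_correlation(tpm: pd.DataFrame, classified: pd.DataFrame) -> dict:
    """Spearman correlation of each non-coding peak with its closest coding peak.

    Constant expression vectors have undefined rank correlation and are
    excluded with a tally. Returns per-class correlation Series and
    median/quartile summaries.
    """
    per_class: dict = {"proximal": {}, "distal": {}}
    excluded = 0
    for pid, row in classified.iterrows():
        label = row["label"]
        if label == "coding":
            continue
        cid = row["closest_coding_peak"]
        if cid is None or cid not in tpm.index or pid not in tpm.index:
            continue
        x = tpm.loc[pid].to_numpy(dtype=float)
        y = tpm.loc[cid].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            excluded += 1
            continue
        rho = sps.spearmanr(x, y).statistic
        per_class[label][pid] = float(rho)
    out = {"excluded": excluded, "summary": {}}
    for label, vals in per_class.items():
        s = pd.Series(vals, dtype=float)
        out[label] = s
        if len(s):
            out["summary"][label] = {
                "median": float(s.median()),
                "q1": float(s.quantile(0.25)),
                "q3": float(s.quantile(0.75)),
                "n": int(len(s)),
            }
    return out


def breadth_of_expression(peaks: pd.DataFrame, atlas_tracks: dict,
                          min_tags: int = 1) -> pd.Series:
    """Number of atlas samples expressing each peak (>= min_tags tags)."""
    expressed = np.zeros(len(peaks), dtype=np.int64)
    for _, track in atlas_tracks.items():
        expressed += count_tags_in_peaks(peaks, track) >= min_tags
    return pd.Series(expressed, index=peaks["peak_id"], name="n_atlas_samples")
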