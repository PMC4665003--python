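"""Reference-cell-line activity calls, chromatin states, TF association and
the cobinding Jaccard network.

A peak is *active* in the reference cell line when it holds at least one
cell CAGE tag and an open-chromatin narrowPeak lies within 1 kb. TF binding
is tested on a strand-oriented window (-600..+400 bp, both bounds inclusive)
around the peak summit with one-sided Fisher tests Bonferroni-corrected over
the TFs; pairs of significant TFs sharing targets above Jaccard 0.5
(strictly) form the cobinding network whose maximal cliques are reported.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import count_tags_in_peaks
from .stats import ContingencyTable

STATE_PRIORITY = ("Promoter", "Enhancer", "Repressive")

DEFAULT_STATE_MAP = {
    "Active_Promoter": "Promoter", "Weak_Promoter": "Promoter",
    "Poised_Promoter": "Promoter",
    "Strong_Enhancer": "Enhancer", "Weak_Enhancer": "Enhancer",
    "Repressed": "Repressive", "Heterochrom": "Repressive",
    "Heterochrom/lo": "Repressive",
}


def _distance_to_nearest(peaks: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """bp gap from each peak interval to the nearest interval (0 if overlapping
    or adjacent)."""
    out = np.full(len(peaks), np.inf)
    by_chrom = {}
    for c, g in intervals.groupby("chrom"):
        g = g.sort_values("start")
        starts = g["start"].to_numpy()
        # running max of ends over intervals sorted by start: allows an O(log)
        # "nearest end to the left" query even with nested intervals
        ends_cummax = np.maximum.accumulate(g["end"].to_numpy())
        by_chrom[c] = (starts, ends_cummax)
    for i, row in enumerate(peaks.itertuples(index=False)):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        starts, ends_cummax = entry
        j = np.searchsorted(starts, row.end)  # first interval starting >= end
        best = np.inf
        if j < len(starts):
            best = starts[j] - row.end
        if j > 0:
            best = min(best, max(row.start - ends_cummax[j - 1], 0))
        out[i] = max(best, 0)
    return out


def call_active(peaks: pd.DataFrame, cell_ctss: pd.DataFrame,
                open_chromatin: pd.DataFrame,
                max_distance: int = 1000) -> pd.DataFrame:
    """Activity calls from cell CAGE tags plus nearby open chromatin.

    active iff (cell_cage_tags >= 1) and (nearest open-chromatin interval at
    most ``max_distance`` bp away; 0 when overlapping). All open-chromatin
    replicates should be concatenated by the caller beforehand.
    """
    tags = count_tags_in_peaks(peaks, cell_ctss)
    dist = _distance_to_nearest(peaks, open_chromatin)
    return pd.DataFrame({
        "cell_cage_tags": tags,
        "nearest_open_peak_distance": dist,
        "active": (tags >= 1) & (dist <= max_distance),
    }, index=peaks["peak_id"])


def chromatin_state_summary(peaks: pd.DataFrame, states: pd.DataFrame,
                            state_map: dict | None = None) -> pd.Series:
    """Single {Promoter, Enhancer, Repressive, Others} label per peak.

    Overlapping segments are merged by the priority Promoter > Enhancer >
    Repressive; anything unmapped (or no overlap) is Others.
    """
    state_map = DEFAULT_STATE_MAP if state_map is None else state_map
    by_chrom = {c: g for c, g in states.groupby("chrom")}
    labels = []
    for row in peaks.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        found = set()
        if grp is not None:
            hit = grp[(grp["start"] < row.end) & (grp["end"] > row.start)]
            found = {state_map.get(s, "Others") for s in hit["state"]}
        label = next((s for s in STATE_PRIORITY if s in found), "Others")
        labels.append(label)
    return pd.Series(labels, index=peaks["peak_id"], name="state")


def binned_signal_profile(peaks: pd.DataFrame, feature_sets: dict,
                          halfwidth: int = 2000, bin_bp: int = 100) -> pd.DataFrame:
    """Mean per-peak feature-midpoint counts in strand-oriented bins.

    Offsets are feature midpoint minus peak summit, mirror-flipped for
    minus-strand peaks; the window is half-open [-halfwidth, +halfwidth).
    Returns a bins x feature-set DataFrame of mean counts per peak.
    """
    n_bins = 2 * halfwidth // bin_bp
    edges = np.arange(-halfwidth, halfwidth + bin_bp, bin_bp)
    index = pd.Index(edges[:-1], name="bin_start")
    out = {}
    summits = peaks[["chrom", "summit", "strand"]]
    for name, feats in feature_sets.items():
        counts = np.zeros(n_bins)
        mids_by_chrom = {
            c: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
            for c, g in feats.groupby("chrom")}
        for row in summits.itertuples(index=False):
            mids = mids_by_chrom.get(row.chrom)
            if mids is None:
                continue
            lo = np.searchsorted(mids, row.summit - halfwidth)
            hi = np.searchsorted(mids, row.summit + halfwidth)
            if lo == hi:
                continue
            off = mids[lo:hi] - row.summit
            if row.strand == "-":
                off = -off
            keep = (off >= -halfwidth) & (off < halfwidth)
            b = (off[keep] + halfwidth) // bin_bp
            np.add.at(counts, b.astype(int), 1)
        out[name] = counts / max(len(peaks), 1)
    return pd.DataFrame(out, index=index)


def _bound_ids(peaks: pd.DataFrame, tf_peaks: pd.DataFrame,
               upstream: int, downstream: int) -> set:
    """Peak ids with a TF-peak midpoint inside [-upstream, +downstream]."""
    mids_by_chrom = {
        c: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
        for c, g in tf_peaks.groupby("chrom")}
    bound = set()
    for row in peaks.itertuples(index=False):
        mids = mids_by_chrom.get(row.chrom)
        if mids is None:
            continue
        if row.strand == "-":
            lo, hi = row.summit - downstream, row.summit + upstream
        else:
            lo, hi = row.summit - upstream, row.summit + downstream
        i = np.searchsorted(mids, lo, side="left")
        j = np.searchsorted(mids, hi, side="right")
        if j > i:
            bound.add(row.peak_id)
    return bound


def tf_association(up_peaks: pd.DataFrame, nonup_peaks: pd.DataFrame,
                   tf_sets: dict, upstream: int = 600, downstream: int = 400,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-TF up/non-up x bound/unbound Fisher association, Bonferroni.

    A peak is bound when a TF-peak midpoint falls in the strand-oriented
    window [-upstream, +downstream] of its summit (closed bounds). The
    target set of a TF is its bound up-regulated peaks. Empty TF sets get
    p = 1 and are tallied via n_bound = 0.
    """
    n_tf = len(tf_sets)
    rows = []
    for tf, feats in tf_sets.items():
        if feats.empty:
            rows.append((tf, 0, len(up_peaks), 0, len(nonup_peaks), 1.0,
                         1.0, False, frozenset()))
            continue
        bound_up = _bound_ids(up_peaks, feats, upstream, downstream)
        bound_non = _bound_ids(nonup_peaks, feats, upstream, downstream)
        a = len(bound_up)
        b = len(up_peaks) - a
        c = len(bound_non)
        d = len(nonup_peaks) - c
        p = ContingencyTable(a, b, c, d).fisher_p("greater")
        p_bonf = min(1.0, p * n_tf)
        rows.append((tf, a, b, c, d, p, p_bonf, p_bonf < alpha,
                     frozenset(bound_up)))
    return pd.DataFrame(rows, columns=[
        "tf", "bound_up", "unbound_up", "bound_nonup", "unbound_nonup",
        "p_one_sided", "p_bonferroni", "significant", "targets"]
        ).set_index("tf")


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def cobinding_network(assoc: pd.DataFrame, jaccard_min: float = 0.5) -> dict:
    """Cobinding network over significant TFs; edges where J > jaccard_min.

    TFs with empty target sets are excluded (tallied). Maximal cliques are
    enumerated; the largest clique(s) are reported sorted for determinism.
    """
    sig = assoc[assoc["significant"]]
    excluded = [tf for tf in sig.index if not sig.at[tf, "targets"]]
    nodes = [tf for tf in sig.index if sig.at[tf, "targets"]]
    if len(nodes) < 2:
        raise ValueError("need >= 2 significant TFs with targets")
    G = nx.Graph()
    G.add_nodes_from(nodes)
    edges = []
    for t1, t2 in itertools.combinations(nodes, 2):
        j = jaccard(sig.at[t1, "targets"], sig.at[t2, "targets"])
        if j > jaccard_min:
            G.add_edge(t1, t2, jaccard=j)
            edges.append((t1, t2, j))
    cliques = sorted((sorted(c) for c in nx.find_cliques(G)),
                     key=lambda c: (-len(c), c))
    max_size = len(cliques[0]) if cliques else 0
    return {"graph": G, "edges": edges, "cliques": cliques,
            "largest_cliques": [c for c in cliques if len(c) == max_size],
            "excluded": excluded}
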