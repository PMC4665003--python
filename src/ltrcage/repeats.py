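"""Strand-aware intersection of CAGE peaks with repeats and its statistics.

Covers the enrichment contingencies (sense/antisense x up/non-up per repeat
family, one-sided Fisher), the FDR-stratified LTR fraction, a randomization
control relocating distal peaks uniformly over the genome, per-subfamily
activation counts against genomic copy number (hypergeometric), the
relative-position histogram of peak summits along elements, and metaelement
tag profiles on long elements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .io_formats import GenomeLayout
from .stats import ContingencyTable, bh_fdr

FAMILIES_IN_SCOPE = ("LTR", "LINE", "SINE", "SVA")


def _repeat_trees(repeats: pd.DataFrame, exclude_internal: bool) -> dict:
    rep = repeats
    if exclude_internal:
        rep = rep[~rep["is_internal"].astype(bool)]
    trees: dict = {}
    for row in rep.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row)
    return trees


def relative_position(summit: int, start: int, end: int, strand: str) -> float:
    """Fraction of element length from the element 5' end to the summit."""
    length = end - start
    if strand == "+":
        return (summit - start) / length
    return (end - summit) / length


def assign_repeat_overlap(peaks: pd.DataFrame, repeats: pd.DataFrame,
                          exclude_internal: bool = True) -> pd.DataFrame:
    """Assign each peak its overlapping repeat element, if any.

    A peak hitting several elements takes the one covering its summit, else
    the largest intersection, ties to the smaller element start. Internal
    ("-int") proviral segments are skipped when ``exclude_internal``.
    Returns a frame indexed by peak_id with element_id, subfamily, family,
    sense_flag and relative_position (NaN when unassigned).
    """
    trees = _repeat_trees(repeats, exclude_internal)
    rows = []
    for row in peaks.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits = list(tree.overlap(row.start, row.end)) if tree else []
        if not hits:
            rows.append((row.peak_id, None, None, "none", False, np.nan))
            continue

        def sort_key(iv):
            covers = iv.begin <= row.summit < iv.end
            inter = min(iv.end, row.end) - max(iv.begin, row.start)
            return (not covers, -inter, iv.begin)

        best = min(hits, key=sort_key).data
        rows.append((row.peak_id, int(best.element_id), best.subfamily,
                     best.family, best.strand == row.strand,
                     relative_position(row.summit, best.start, best.end,
                                       best.strand)))
    return pd.DataFrame(rows, columns=[
        "peak_id", "element_id", "subfamily", "family", "sense_flag",
        "relative_position"]).set_index("peak_id")


def enrichment_tables(overlaps: pd.DataFrame, up_ids, nonup_ids,
                      families=FAMILIES_IN_SCOPE,
                      orientations=("sense", "antisense")) -> pd.DataFrame:
    """Per family x orientation contingency of up vs non-up distal peaks.

    Cells: a = up peaks in category, b = up not in category, c = non-up in
    category, d = non-up not. One-sided Fisher tests enrichment among up.
    """
    up_ids, nonup_ids = list(up_ids), list(nonup_ids)
    if not up_ids or not nonup_ids:
        raise ValueError("both up and non-up partitions must be non-empty")
    up = overlaps.loc[overlaps.index.intersection(up_ids)]
    non = overlaps.loc[overlaps.index.intersection(nonup_ids)]
    rows = []
    for family in families:
        for orient in orientations:
            sense = orient == "sense"

            def in_cat(df):
                return int(((df["family"] == family)
                            & (df["sense_flag"] == sense)).sum())

            a, c = in_cat(up), in_cat(non)
            table = ContingencyTable(a, len(up) - a, c, len(non) - c)
            lo, hi = table.ci95()
            rows.append((family, orient, a, len(up) - a, c, len(non) - c,
                         a / len(up), c / len(non), table.odds_ratio, lo, hi,
                         table.fisher_p("greater")))
    return pd.DataFrame(rows, columns=[
        "family", "orientation", "a", "b", "c", "d", "frac_up", "frac_nonup",
        "odds_ratio", "ci95_low", "ci95_high", "p_fisher"])


def fdr_stratified_fractions(overlaps: pd.DataFrame, diff: pd.DataFrame,
                             distal_ids,
                             edges=(0.05, 1e-3, 1e-5, 1e-8),
                             family: str = "LTR") -> pd.DataFrame:
    """LTR-sense fraction of distal peaks per FDR significance bin."""
    distal_ids = [i for i in distal_ids if i in diff.index]
    fdr = diff.loc[distal_ids, "fdr_bh"]
    bins = [np.inf] + sorted(edges, reverse=True) + [0.0]
    rows = []
    ov = overlaps.reindex(distal_ids)
    is_cat = (ov["family"] == family) & ov["sense_flag"]
    for hi, lo in zip(bins[:-1], bins[1:]):
        mask = (fdr < hi) & (fdr >= lo)
        n = int(mask.sum())
        k = int(is_cat[mask.to_numpy()].sum())
        if n == 0:
            rows.append((hi, lo, 0, 0, np.nan, np.nan, np.nan))
            continue
        ci_lo, ci_hi = proportion_confint(k, n, method="wilson")
        rows.append((hi, lo, n, k, k / n, ci_lo, ci_hi))
    return pd.DataFrame(rows, columns=["fdr_below", "fdr_at_least", "n_peaks",
                                       "n_in_category", "fraction",
                                       "ci_low", "ci_high"])


def _merged_intervals(repeats: pd.DataFrame) -> dict:
    """Merged (chrom, strand) -> (starts, ends) sorted arrays."""
    merged = {}
    for (chrom, strand), grp in repeats.groupby(["chrom", "strand"]):
        ivs = sorted(zip(grp["start"], grp["end"]))
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        arr = np.array(out, dtype=np.int64).reshape(-1, 2)
        merged[(chrom, strand)] = (arr[:, 0], arr[:, 1])
    return merged


def _overlaps_any(starts, ends, qs, qe) -> np.ndarray:
    """Vectorized: does [qs_i, qe_i) intersect any merged interval?"""
    if len(starts) == 0:
        return np.zeros(len(qs), dtype=bool)
    idx = np.searchsorted(starts, qe, side="left") - 1
    hit = np.zeros(len(qs), dtype=bool)
    ok = idx >= 0
    hit[ok] = ends[idx[ok]] > qs[ok]
    return hit


def randomize_distal_peaks(peaks: pd.DataFrame, repeats: pd.DataFrame,
                           genome: GenomeLayout, n_reps: int, seed: int,
                           family: str = "LTR", sense: bool = True,
                           randomize_strand: bool = True,
                           exclude_internal: bool = True) -> dict:
    """Null distribution of family-overlap fractions for relocated peaks.

    Each replicate relocates every peak to a uniform random genomic position
    (chromosome chosen with probability proportional to its length, i.e.
    uniform per bp), preserving peak length; strands are redrawn uniformly
    unless ``randomize_strand`` is False. Overlap is sense-orientation
    intersection with the merged elements of ``family``.
    """
    rng = np.random.default_rng(seed)
    rep = repeats[repeats["family"] == family]
    if exclude_internal:
        rep = rep[~rep["is_internal"].astype(bool)]
    merged = _merged_intervals(rep)
    lengths = (peaks["end"] - peaks["start"]).to_numpy()
    strands = peaks["strand"].to_numpy()
    chrom_lengths = np.array(genome.chrom_lengths, dtype=np.int64)
    if (lengths > chrom_lengths.max()).any():
        raise ValueError("peak longer than every chromosome")
    probs = chrom_lengths / chrom_lengths.sum()
    fractions = np.empty(n_reps)
    n = len(peaks)
    for rep_i in range(n_reps):
        ci = rng.choice(len(chrom_lengths), size=n, p=probs)
        max_start = chrom_lengths[ci] - lengths
        if (max_start < 0).any():
            raise ValueError("peak longer than chosen chromosome")
        qs = (rng.random(n) * (max_start + 1)).astype(np.int64)
        qe = qs + lengths
        st = (np.where(rng.random(n) < 0.5, "+", "-")
              if randomize_strand else strands)
        hit = np.zeros(n, dtype=bool)
        for k, (chrom, strand) in enumerate(
                (c, s) for c in genome.chrom_names for s in ("+", "-")):
            key = (chrom, strand)
            if key not in merged:
                continue
            mask = (ci == genome.chrom_names.index(chrom))
            if sense:
                mask &= (st == strand)
            if not mask.any():
                continue
            starts, ends = merged[key]
            hit[mask] |= _overlaps_any(starts, ends, qs[mask], qe[mask])
        fractions[rep_i] = hit.mean()
    return {"fractions": fractions, "mean": float(fractions.mean()),
            "sd": float(fractions.std(ddof=1)) if n_reps > 1 else 0.0}


def empirical_p(null_fractions: np.ndarray, observed: float) -> float:
    """Upper-tail empirical p with the +1 correction."""
    null_fractions = np.asarray(null_fractions)
    return float((1 + (null_fractions >= observed).sum())
                 / (1 + len(null_fractions)))


def subfamily_activation(overlaps: pd.DataFrame, up_ids,
                         repeats: pd.DataFrame) -> pd.DataFrame:
    """Distinct activated elements per subfamily vs genomic copy number.

    Enrichment of each subfamily's activated-element count against its copy
    number by the hypergeometric test (population = all catalog elements,
    successes = elements hit by up-regulated peaks), BH across subfamilies.
    Elements are the unit: two peaks on one element count once (the peak
    count is reported separately).
    """
    up = overlaps.loc[overlaps.index.intersection(list(up_ids))]
    up = up.dropna(subset=["element_id"])
    element_subfam = repeats.set_index("element_id")["subfamily"]
    activated_elements = up.groupby("subfamily")["element_id"].nunique()
    peak_counts = up.groupby("subfamily").size()
    copy_numbers = element_subfam.value_counts()
    for sub in activated_elements.index:
        if sub not in copy_numbers.index:
            raise KeyError(f"subfamily {sub!r} absent from repeat catalog")
    M = int(len(element_subfam))
    K = int(up["element_id"].nunique())
    rows = []
    for sub, n_copies in copy_numbers.items():
        k = int(activated_elements.get(sub, 0))
        p = 1.0 if k == 0 else float(sps.hypergeom.sf(k - 1, M, K, n_copies))
        rows.append((sub, k, int(peak_counts.get(sub, 0)), int(n_copies), p))
    out = pd.DataFrame(rows, columns=["subfamily", "n_activated_elements",
                                      "n_peaks", "copy_number", "p_hyper"])
    out["fdr_bh"] = bh_fdr(out["p_hyper"].to_numpy())
    return out.sort_values("p_hyper").reset_index(drop=True)


def relative_position_profile(overlaps: pd.DataFrame, subfamily: str,
                              bin_width: float = 0.05) -> dict:
    """Histogram (5% bins) of summit relative positions along a subfamily."""
    vals = overlaps.loc[overlaps["subfamily"] == subfamily,
                        "relative_position"].dropna().to_numpy()
    if len(vals) == 0:
        raise ValueError(f"no overlaps for subfamily {subfamily!r}")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    hist, _ = np.histogram(np.clip(vals, 0, np.nextafter(1.0, 0)), bins=edges)
    density = hist / hist.sum()
    mode = int(np.argmax(hist))
    return {"edges": edges, "hist": hist, "density": density,
            "mode_bin": (float(edges[mode]), float(edges[mode + 1])),
            "n": int(len(vals))}


def metaelement_profile(tracks_by_group: dict, elements: pd.DataFrame,
                        library_sizes: pd.Series, min_length: int = 5000,
                        n_bins: int = 100) -> dict:
    """Sense/antisense CAGE tag density along long elements, per group.

    Tags are binned by their relative position along each qualifying element
    (5'->3' on the element strand); profiles are normalized to tags per
    million library tags per group. Returns group -> {"sense": array,
    "antisense": array}.
    """
    qual = elements[(elements["end"] - elements["start"]) >= min_length]
    if qual.empty:
        raise ValueError(f"no elements of length >= {min_length}")
    out = {}
    for group, tracks in tracks_by_group.items():
        prof = {"sense": np.zeros(n_bins), "antisense": np.zeros(n_bins)}
        total_lib = float(sum(library_sizes[s] for s in tracks))
        for sample, track in tracks.items():
            if track.empty:
                continue
            for (chrom, strand), grp in track.groupby(["chrom", "strand"]):
                pos = grp["pos"].to_numpy()
                cnt = grp["count"].to_numpy()
                sub = qual[qual["chrom"] == chrom]
                for el in sub.itertuples(index=False):
                    lo = np.searchsorted(pos, el.start)
                    hi = np.searchsorted(pos, el.end)
                    if lo == hi:
                        continue
                    p = pos[lo:hi]
                    c = cnt[lo:hi]
                    rel = ((p - el.start) if el.strand == "+"
                           else (el.end - 1 - p)) / (el.end - el.start)
                    b = np.minimum((rel * n_bins).astype(int), n_bins - 1)
                    channel = ("sense" if strand == el.strand else "antisense")
                    np.add.at(prof[channel], b, c)
        for channel in prof:
            prof[channel] = prof[channel] / total_lib * 1e6
        out[group] = prof
    return out
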