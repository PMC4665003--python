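"""Density-based clustering of CTSS positions into CAGE peaks.

The clustering is the Paraclu-style weakest-link segmentation: each maximal
run of tag sites on one (chromosome, strand) is recursively split at its
minimum-density proper prefix or suffix. Every run visited is a candidate
cluster characterised by the density at which it becomes maximal (``d_form``,
inherited from the parent's break density, 0 at the root) and the density at
which it splits (``d_break``; +inf for single sites). Density of a run is
total tags / site span, with span = last_pos - first_pos + 1 so that single
sites are well defined.

Reported peaks satisfy three filters — total tags >= min_tags, span <=
max_length, and d_break/d_form >= min_fold (d_form = 0 always passes) — and
are then simplified by dropping any reported cluster strictly contained in
another reported cluster on the same strand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CTSS_COLUMNS

PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "strand", "n_sites",
                "total_tags", "d_form", "d_break", "summit"]


def _segment_run(pos: np.ndarray, cnt: np.ndarray) -> list:
    """Weakest-link segmentation of one sorted site run.

    Returns (first, last, n_sites, total, d_form, d_break) candidate tuples.
    At equal prefix/suffix break densities the split is at the prefix
    boundary; within prefixes/suffixes the leftmost minimum wins.
    """
    out = []
    stack = [(0, len(pos), 0.0)]
    while stack:
        b, e, d_form = stack.pop()
        m = e - b
        if m == 1:
            out.append((pos[b], pos[b], 1, int(cnt[b]), d_form, np.inf))
            continue
        p = pos[b:e]
        c = cnt[b:e]
        cum = np.cumsum(c)
        total = int(cum[-1])
        # proper prefixes [0..i], i = 0..m-2; proper suffixes [j..m-1], j = 1..m-1
        pref_dens = cum[:-1] / (p[:-1] - p[0] + 1.0)
        suf_dens = (total - cum[:-1]) / (p[-1] - p[1:] + 1.0)
        ip = int(np.argmin(pref_dens))
        js = int(np.argmin(suf_dens))
        pref_min = pref_dens[ip]
        suf_min = suf_dens[js]
        if pref_min <= suf_min:
            d_break = float(pref_min)
            split = b + ip + 1
        else:
            d_break = float(suf_min)
            split = b + js + 1
        out.append((p[0], p[-1], m, total, d_form, d_break))
        # children become maximal only above every ancestor's break density
        child_form = max(d_break, d_form)
        stack.append((b, split, child_form))
        stack.append((split, e, child_form))
    return out


def paraclu_cluster(ctss: pd.DataFrame, min_tags: int = 10,
                    min_fold: float = 2.0, max_length: int = 500) -> pd.DataFrame:
    """Cluster pooled stranded CTSS counts into CAGE peaks.

    ``ctss`` must be sorted by (chrom, pos, strand) with counts >= 1; the
    result is a peak table with half-open [start, end) intervals, formation
    and break densities, and the summit (position of the maximum pooled
    count, leftmost on ties).
    """
    if ctss.empty:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    if (ctss["count"] < 1).any():
        raise ValueError("CTSS counts must be >= 1")
    rows = []
    for (chrom, strand), grp in ctss.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        cnt = grp["count"].to_numpy(dtype=np.int64)
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"CTSS positions not sorted/unique on "
                             f"{chrom}{strand}")
        candidates = _segment_run(pos, cnt)
        # a candidate exists only if some achievable density (the density of
        # some site run) falls in (d_form, d_break]; a finite break density
        # is itself achievable, while a single site (infinite break) needs an
        # achievable density above its formation density — the largest
        # achievable density on a strand is the largest single-site count
        d_max = float(cnt.max())
        kept = []
        for first, last, n_sites, total, d_form, d_break in candidates:
            if np.isinf(d_break):
                if d_form >= d_max:
                    continue
            elif d_break <= d_form:
                continue
            span = last - first + 1
            if total < min_tags or span > max_length:
                continue
            if d_form > 0 and not (d_break / d_form >= min_fold):
                continue
            kept.append((first, last, n_sites, total, d_form, d_break))
        # simplify: drop clusters strictly contained in another kept cluster
        kept.sort(key=lambda t: (t[0], -t[1]))
        outer_end = -1
        for first, last, n_sites, total, d_form, d_break in kept:
            if last <= outer_end:
                continue  # contained in a previously kept outer cluster
            outer_end = last
            lo = int(np.searchsorted(pos, first))
            hi = int(np.searchsorted(pos, last, side="right"))
            summit = int(pos[lo + int(np.argmax(cnt[lo:hi]))])
            rows.append((chrom, int(first), int(last) + 1, strand, n_sites,
                         total, d_form, d_break, summit))
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS[1:])
    peaks = peaks.sort_values(["chrom", "start", "strand"],
                              kind="mergesort").reset_index(drop=True)
    peaks.insert(0, "peak_id", [f"peak_{i:05d}" for i in range(len(peaks))])
    return peaks


def pool_ctss(tracks: dict) -> pd.DataFrame:
    """Sum per-sample CTSS tracks into one pooled track."""
    frames = [t for t in tracks.values() if not t.empty]
    if not frames:
        return pd.DataFrame(columns=CTSS_COLUMNS)
    pooled = pd.concat(frames, ignore_index=True)
    return (pooled.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
                  .sum()
                  .sort_values(["chrom", "pos", "strand"], kind="mergesort")
                  .reset_index(drop=True))


def count_tags_in_peaks(peaks: pd.DataFrame, ctss: pd.DataFrame) -> np.ndarray:
    """Tags with 5' position inside each peak's [start, end) on its strand."""
    counts = np.zeros(len(peaks), dtype=np.int64)
    if ctss.empty or peaks.empty:
        return counts
    for (chrom, strand), grp in ctss.groupby(["chrom", "strand"]):
        mask = (peaks["chrom"] == chrom) & (peaks["strand"] == strand)
        if not mask.any():
            continue
        pos = grp["pos"].to_numpy()
        cum = np.concatenate(([0], np.cumsum(grp["count"].to_numpy())))
        lo = np.searchsorted(pos, peaks.loc[mask, "start"].to_numpy())
        hi = np.searchsorted(pos, peaks.loc[mask, "end"].to_numpy())
        counts[mask.to_numpy()] = cum[hi] - cum[lo]
    return counts


def quantify_peaks(peaks: pd.DataFrame, tracks: dict,
                   library_sizes: pd.Series) -> tuple:
    """Per-sample raw counts and tpm for each peak.

    ``tracks`` maps sample_id -> CTSS DataFrame. tpm = count / library_size
    * 1e6. Raises KeyError if a track's sample is missing from the sheet.
    """
    counts = {}
    for sample, track in tracks.items():
        if sample not in library_sizes.index:
            raise KeyError(f"sample {sample!r} missing from sample sheet")
        counts[sample] = count_tags_in_peaks(peaks, track)
    count_matrix = pd.DataFrame(counts, index=peaks["peak_id"])
    tpm_matrix = count_matrix / library_sizes[count_matrix.columns] * 1e6
    return count_matrix, tpm_matrix


def filter_working_set(tpm: pd.DataFrame, counts: pd.DataFrame,
                       tumor_samples, min_tpm: float = 1.0,
                       min_samples: int = 2) -> tuple:
    """Expression filters defining the working peak set.

    Keep peaks whose tpm exceeds ``min_tpm`` in at least one tumor sample AND
    that have >= 1 tag in at least ``min_samples`` tumor samples. Returns
    (kept peak ids, tallies dict).
    """
    tumor_samples = list(tumor_samples)
    if not tumor_samples:
        raise ValueError("no tumor samples supplied")
    max_tpm = tpm[tumor_samples].max(axis=1)
    n_expressed = (counts[tumor_samples] >= 1).sum(axis=1)
    keep = (max_tpm > min_tpm) & (n_expressed >= min_samples)
    tallies = {"total": int(len(keep)), "kept": int(keep.sum()),
               "dropped": int((~keep).sum())}
    return tpm.index[keep], tallies
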