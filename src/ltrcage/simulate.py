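"""Synthetic cohorts with planted structure for every pipeline stage.

The generator emulates the shape of a CAGE liver-tumor study: a small genome
carrying protein-coding genes and a RepeatMasker-style repeat catalog; a
designated LTR subfamily whose copies host planted tumor-activated promoters
at a fixed relative position (70% of element length, strand-aware);
multi-sample CTSS tracks with negative-binomial count noise (variance
mu + phi*mu^2) and sparse uniform background tags; clinical covariates drawn
conditionally on each tumor's latent LTR-activity tier; and regulatory
tracks (TF ChIP-style narrowPeaks with a planted fully-cobinding clique,
open chromatin, chromatin states, and a cell-line CTSS track).

Every draw flows through one numpy Generator seeded from the plan, so a
fixed seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CTSS_COLUMNS, REPEAT_COLUMNS, GeneModel, GenomeLayout

TAG_WINDOW_WEIGHTS = (0.1, 0.15, 0.5, 0.15, 0.1)  # 5-bp summit-peaked window


@dataclass(frozen=True)
class SubfamilySpec:
    name: str
    family: str
    copy_number: int
    length_min: int
    length_max: int

    def __post_init__(self):
        if self.copy_number < 1:
            raise ValueError("copy numbers must be >= 1")
        if not (0 < self.length_min <= self.length_max):
            raise ValueError("bad length range")


def default_subfamilies() -> list:
    return [
        SubfamilySpec("LTR12C-like", "LTR", 80, 1000, 1600),
        SubfamilySpec("LTR7-like", "LTR", 60, 400, 500),
        SubfamilySpec("HERVH-int-like", "LTR", 40, 2000, 3000),
        SubfamilySpec("L1-full-like", "LINE", 30, 6000, 6500),
        SubfamilySpec("L1-trunc-like", "LINE", 120, 500, 1500),
        SubfamilySpec("Alu-like", "SINE", 250, 280, 320),
        SubfamilySpec("MIR-like", "SINE", 120, 150, 260),
        SubfamilySpec("SVA-like", "SVA", 25, 1000, 1600),
    ]


def default_clinical_model() -> dict:
    # tier-conditional Bernoulli probabilities; recurrence defaults reproduce
    # 10/16 for high-tier and 2/14 for low-tier cohorts in expectation
    return {
        "recurrence": {"high": 10 / 16, "intermediate": 0.35, "low": 2 / 14},
        "viral_etiology": {"high": 0.9, "intermediate": 0.6, "low": 1 / 3},
        "age_ge_55": {"high": 0.8, "intermediate": 0.6, "low": 0.4},
        "poor_differentiation": {"high": 0.7, "intermediate": 0.4, "low": 0.15},
    }


@dataclass
class SimulationPlan:
    genome: GenomeLayout = field(
        default_factory=lambda: GenomeLayout(("chrS1", "chrS2"),
                                             (5_000_000, 5_000_000)))
    n_tumor: int = 20
    n_nontumor: int = 20
    n_normal: int = 5
    n_coding_genes: int = 200
    subfamilies: list = field(default_factory=default_subfamilies)
    activated_subfamily: str = "LTR12C-like"
    n_activated: int = 60
    promoter_offset_frac: float = 0.70
    fold_change: float = 16.0
    activated_mu_range: tuple = (50.0, 200.0)
    coding_mu_range: tuple = (20.0, 200.0)
    n_weak_activated: int = 40
    weak_fold_change: float = 3.0
    weak_mu_range: tuple = (10.0, 40.0)
    n_background_distal: int = 150
    background_ltr_fraction: float = 0.06
    background_mu_range: tuple = (5.0, 30.0)
    n_divergent: int = 40
    divergent_offset: int = 250
    divergent_mu_range: tuple = (5.0, 30.0)
    coexpression_sigma: float = 0.4
    feature_spacing: int = 6000
    n_line_antisense: int = 20
    line_antisense_mu: float = 10.0
    phi: float = 0.1
    background_rate_per_mb: float = 50.0
    library_size_range: tuple = (900_000.0, 1_100_000.0)
    tier_fractions: dict = field(default_factory=lambda: {
        "high": 0.32, "intermediate": 0.40, "low": 0.28})
    tier_activity: dict = field(default_factory=lambda: {
        "high": 1.0, "intermediate": 0.3, "low": 0.0})
    clinical_model: dict = field(default_factory=default_clinical_model)
    n_clique_tfs: int = 6
    n_background_tfs: int = 13
    p_clique: float = 0.9
    p_background: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        for name, probs in self.clinical_model.items():
            for tier, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}/{tier}: probability outside [0,1]")
        for p in (self.p_clique, self.p_background):
            if not (0.0 <= p <= 1.0):
                raise ValueError("TF binding probabilities must be in [0,1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Planted labels sufficient to score every downstream stage."""

    loci: pd.DataFrame          # locus_id, kind, chrom, tss, strand, mu, fold, ...
    sample_tiers: pd.Series     # sample_id -> tier (tumor samples)
    tf_targets: dict            # tf name -> set of activated locus ids
    clique_tfs: list


GENE_SPAN = 3000
GENE_EXONS = ((0, 200), (1400, 1600), (2800, 3000))


def _make_gene(gene_id: str, chrom: str, start: int, strand: str) -> GeneModel:
    exons = [(start + s, start + e) for s, e in GENE_EXONS]
    tss = start if strand == "+" else start + GENE_SPAN - 1
    return GeneModel(gene_id, chrom, strand, tss, exons, "protein_coding")


def planted_tss(start: int, end: int, strand: str, frac: float) -> int:
    """Promoter position at ``frac`` of element length from its 5' end."""
    length = end - start
    off = int(round(frac * length))
    return start + off if strand == "+" else start + (length - off)


def simulate_genome_and_annotations(plan: SimulationPlan):
    """Place genes and repeat copies on the genome without overlap.

    Returns (genes, repeats frame, truth frame of planted loci). Features
    keep >= 1 kb spacing; exceeding genome capacity raises ValueError.
    """
    rng = plan.rng()
    n_bg_ltr = int(round(plan.background_ltr_fraction * plan.n_background_distal))
    n_slots = plan.n_weak_activated + (plan.n_background_distal - n_bg_ltr)
    features = [("gene", i, GENE_SPAN) for i in range(plan.n_coding_genes)]
    features += [("slot", i, 1) for i in range(n_slots)]
    for spec in plan.subfamilies:
        lengths = rng.integers(spec.length_min, spec.length_max + 1,
                               size=spec.copy_number)
        features.extend(("repeat", spec, int(l)) for l in lengths)
    rng.shuffle(features)

    spacing = plan.feature_spacing
    needed = sum(l for _, _, l in features) + spacing * (len(features) + 1)
    if needed > plan.genome.total_bp:
        raise ValueError(f"genome too small: need {needed} bp, "
                         f"have {plan.genome.total_bp}")

    # spread features over chromosomes proportionally, randomizing gaps
    placements = []
    start_idx = 0
    remaining = len(features)
    for ci, (chrom, length) in enumerate(zip(plan.genome.chrom_names,
                                             plan.genome.chrom_lengths)):
        if ci == len(plan.genome.chrom_names) - 1:
            take = remaining
        else:
            take = int(round(remaining * length / sum(
                plan.genome.chrom_lengths[ci:])))
        chunk = features[start_idx:start_idx + take]
        start_idx += take
        remaining -= take
        used = sum(l for _, _, l in chunk) + spacing * (len(chunk) + 1)
        if used > length:
            raise ValueError(f"{chrom}: features exceed chromosome capacity")
        slack = length - used
        extras = rng.multinomial(slack, np.full(len(chunk) + 1,
                                                1.0 / (len(chunk) + 1)))
        cursor = 0
        for k, (kind, payload, flen) in enumerate(chunk):
            cursor += spacing + int(extras[k])
            placements.append((kind, payload, chrom, cursor, cursor + flen))
            cursor += flen

    genes, repeat_rows, loci_rows, slots = [], [], [], []
    gi = 0
    for kind, payload, chrom, start, end in placements:
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "gene":
            g = _make_gene(f"gene_{gi:04d}", chrom, start, strand)
            gi += 1
            genes.append(g)
        elif kind == "slot":
            slots.append((chrom, start, strand))
        else:
            spec = payload
            repeat_rows.append((chrom, start, end, strand, spec.name,
                                spec.family, spec.name.endswith("-int")))
    repeats = pd.DataFrame(repeat_rows, columns=REPEAT_COLUMNS[1:])
    repeats = repeats.sort_values(["chrom", "start"]).reset_index(drop=True)
    repeats.insert(0, "element_id", np.arange(len(repeats)))

    def _log_uniform(lo_hi, size):
        return np.exp(rng.uniform(np.log(lo_hi[0]), np.log(lo_hi[1]), size))

    # strongly activated LTR promoters on copies of the designated subfamily
    cand = repeats.index[repeats["subfamily"] == plan.activated_subfamily]
    if len(cand) < plan.n_activated:
        raise ValueError(f"{plan.activated_subfamily}: only {len(cand)} copies "
                         f"for {plan.n_activated} planted activations")
    chosen = set(rng.choice(cand.to_numpy(), size=plan.n_activated,
                            replace=False).tolist())
    mu_act = _log_uniform(plan.activated_mu_range, plan.n_activated)
    for j, ridx in enumerate(sorted(chosen)):
        row = repeats.loc[ridx]
        tss = planted_tss(int(row.start), int(row.end), row.strand,
                          plan.promoter_offset_frac)
        loci_rows.append((f"act_{j:03d}", "activated", row.chrom, tss,
                          row.strand, float(mu_act[j]), plan.fold_change,
                          row.subfamily, int(row.element_id), None))
    # weakly activated intergenic ncRNA promoters (up in every tumor)
    mu_weak = _log_uniform(plan.weak_mu_range, plan.n_weak_activated)
    for j in range(plan.n_weak_activated):
        chrom, pos, strand = slots[j]
        loci_rows.append((f"weak_{j:03d}", "weak_activated", chrom, pos,
                          strand, float(mu_weak[j]), plan.weak_fold_change,
                          None, None, None))
    # background distal promoters, constant across groups; a fraction sit in
    # non-activated non-internal LTR copies in sense orientation
    n_bg_ltr = int(round(plan.background_ltr_fraction * plan.n_background_distal))
    free_ltr = [i for i in repeats.index[
        (repeats["family"] == "LTR") & ~repeats["is_internal"]]
        if i not in chosen]
    bg_ltr = sorted(rng.choice(np.array(free_ltr), size=min(n_bg_ltr, len(free_ltr)),
                               replace=False).tolist())
    mu_bg = _log_uniform(plan.background_mu_range, plan.n_background_distal)
    for j in range(plan.n_background_distal):
        if j < len(bg_ltr):
            row = repeats.loc[bg_ltr[j]]
            tss = planted_tss(int(row.start), int(row.end), row.strand,
                              plan.promoter_offset_frac)
            loci_rows.append((f"bg_{j:03d}", "background", row.chrom, tss,
                              row.strand, float(mu_bg[j]), 1.0, row.subfamily,
                              int(row.element_id), None))
        else:
            chrom, pos, strand = slots[plan.n_weak_activated + j - len(bg_ltr)]
            loci_rows.append((f"bg_{j:03d}", "background", chrom, pos, strand,
                              float(mu_bg[j]), 1.0, None, None, None))
    # housekeeping coding promoters; the first n_divergent genes get a
    # divergent antisense partner sharing a per-sample latent factor
    mu_cod = _log_uniform(plan.coding_mu_range, len(genes))
    for j, g in enumerate(genes):
        loci_rows.append((f"hk_{j:04d}", "housekeeping", g.chrom, g.tss_pos,
                          g.strand, float(mu_cod[j]), 1.0, None, None,
                          g.gene_id))
    mu_div = _log_uniform(plan.divergent_mu_range,
                          min(plan.n_divergent, len(genes)))
    for j in range(min(plan.n_divergent, len(genes))):
        g = genes[j]
        if g.strand == "+":
            pos, strand = g.tss_pos - plan.divergent_offset, "-"
        else:
            pos, strand = g.tss_pos + plan.divergent_offset, "+"
        loci_rows.append((f"div_{j:03d}", "divergent", g.chrom, pos, strand,
                          float(mu_div[j]), 1.0, None, None, g.gene_id))
    # weak antisense promoters near the 5' end of long LINE copies
    long_lines = repeats.index[(repeats["family"] == "LINE")
                               & (repeats["end"] - repeats["start"] >= 5000)]
    n_as = min(plan.n_line_antisense, len(long_lines))
    for j, ridx in enumerate(np.sort(rng.choice(long_lines.to_numpy(),
                                                size=n_as, replace=False))):
        row = repeats.loc[ridx]
        tss = planted_tss(int(row.start), int(row.end), row.strand, 0.05)
        anti = "-" if row.strand == "+" else "+"
        loci_rows.append((f"lineas_{j:03d}", "line_antisense", row.chrom, tss,
                          anti, plan.line_antisense_mu, 1.0, row.subfamily,
                          int(row.element_id), None))
    loci = pd.DataFrame(loci_rows, columns=[
        "locus_id", "kind", "chrom", "tss", "strand", "mu", "fold",
        "subfamily", "element_id", "latent_group"]).set_index("locus_id")
    return genes, repeats, loci


def _nb_draw(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12)))


def _sample_names(plan: SimulationPlan) -> pd.DataFrame:
    rows = []
    for i in range(plan.n_tumor):
        rows.append((f"T{i + 1:02d}", "tumor", f"pair{i + 1:02d}"))
    for i in range(plan.n_nontumor):
        pair = f"pair{i + 1:02d}" if i < plan.n_tumor else None
        rows.append((f"N{i + 1:02d}", "nontumor", pair))
    for i in range(plan.n_normal):
        rows.append((f"C{i + 1:02d}", "normal", None))
    return pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"]
                        ).set_index("sample_id")


def _assign_tiers(plan: SimulationPlan, rng) -> pd.Series:
    n = plan.n_tumor
    counts = {t: int(round(f * n)) for t, f in plan.tier_fractions.items()}
    drift = n - sum(counts.values())
    counts["intermediate"] = counts.get("intermediate", 0) + drift
    labels = sum(([t] * c for t, c in counts.items()), [])
    rng.shuffle(labels)
    return pd.Series(labels, index=[f"T{i + 1:02d}" for i in range(n)],
                     name="tier")


def simulate_ctss(plan: SimulationPlan, genes, repeats, loci):
    """Draw per-sample CTSS tracks, the sample sheet and the ground truth.

    Locus means are mu * s_j * activity, s_j the sample's relative library
    size, activity = 1 + (fold - 1) * tier multiplier for activated loci in
    tumor samples and 1 otherwise. Each locus total is NB(mean, phi) and is
    spread multinomially over a 5-bp window peaked at the planted summit;
    background tags land uniformly at ``background_rate_per_mb``.
    """
    rng = plan.rng()
    rng = np.random.default_rng(rng.integers(2 ** 31))  # decouple from placement
    sheet = _sample_names(plan)
    lo, hi = plan.library_size_range
    sheet["library_size"] = rng.integers(int(lo), int(hi) + 1, size=len(sheet))
    tiers = _assign_tiers(plan, rng)
    sheet["tier"] = tiers.reindex(sheet.index)

    chrom_len = plan.genome.lengths
    mean_lib = float(sheet["library_size"].mean())
    groups_arr = loci["latent_group"].to_numpy()
    group_names = sorted({g for g in groups_arr if g is not None})
    group_idx = {g: i for i, g in enumerate(group_names)}
    sigma = plan.coexpression_sigma
    tracks = {}
    for sample, srow in sheet.iterrows():
        s_j = srow["library_size"] / mean_lib
        is_tumor = srow["group"] == "tumor"
        mult = plan.tier_activity.get(srow["tier"], 0.0) if is_tumor else 0.0
        act = 1.0 + (loci["fold"].to_numpy() - 1.0) * (
            mult * (loci["kind"] == "activated").to_numpy()
            + (1.0 if is_tumor else 0.0)
            * (loci["kind"] == "weak_activated").to_numpy())
        # shared per-sample latent factor couples a gene and its divergent
        # partner (mean-1 lognormal)
        factors = np.exp(rng.normal(-sigma ** 2 / 2, sigma,
                                    size=len(group_names)))
        latent = np.array([factors[group_idx[g]] if g is not None else 1.0
                           for g in groups_arr])
        means = loci["mu"].to_numpy() * s_j * act * latent
        totals = _nb_draw(rng, means, plan.phi)
        pos_list, strand_list, cnt_list = [], [], []
        for (tss, strand, chrom), total in zip(
                loci[["tss", "strand", "chrom"]].itertuples(index=False),
                totals):
            if total == 0:
                continue
            window = rng.multinomial(int(total), TAG_WINDOW_WEIGHTS)
            offs = np.arange(-2, 3)
            if strand == "-":
                offs = offs[::-1]
            for off, c in zip(offs, window):
                p = tss + off
                if c > 0 and 0 <= p < chrom_len[chrom]:
                    pos_list.append((chrom, p, strand, int(c)))
        # uniform background noise
        n_bg = rng.poisson(plan.background_rate_per_mb
                           * plan.genome.total_bp / 1e6 * s_j)
        if n_bg:
            cum = np.cumsum(plan.genome.chrom_lengths)
            flat = rng.integers(0, plan.genome.total_bp, size=n_bg)
            ci = np.searchsorted(cum, flat, side="right")
            offset = flat - np.concatenate(([0], cum[:-1]))[ci]
            strands = np.where(rng.random(n_bg) < 0.5, "+", "-")
            for c, o, st in zip(ci, offset, strands):
                pos_list.append((plan.genome.chrom_names[c], int(o), st, 1))
        track = pd.DataFrame(pos_list, columns=CTSS_COLUMNS)
        if not track.empty:
            track = (track.groupby(["chrom", "pos", "strand"],
                                   as_index=False)["count"].sum()
                          .sort_values(["chrom", "pos", "strand"],
                                       kind="mergesort")
                          .reset_index(drop=True))
        tracks[sample] = track

    truth = GroundTruth(loci=loci, sample_tiers=tiers, tf_targets={},
                        clique_tfs=[])
    return tracks, sheet, truth


def simulate_clinical(plan: SimulationPlan, sheet: pd.DataFrame,
                      truth: GroundTruth) -> pd.DataFrame:
    """Draw tier-conditional binary covariates for tumor samples."""
    rng = np.random.default_rng(plan.rng().integers(2 ** 31) + 1)
    sheet = sheet.copy()
    for cov, probs in plan.clinical_model.items():
        vals = {}
        for sample, tier in truth.sample_tiers.items():
            vals[sample] = int(rng.random() < probs[tier])
        sheet[cov] = pd.Series(vals).reindex(sheet.index)
    return sheet


def simulate_regulatory_tracks(plan: SimulationPlan, truth: GroundTruth,
                               genome: GenomeLayout | None = None):
    """TF narrowPeaks, open chromatin, chromatin states and a cell CTSS track.

    A clique of ``n_clique_tfs`` TFs binds each activated locus with
    probability ``p_clique``, with the peak midpoint within [-100, 0) bp of
    the summit on the locus strand; background TFs bind any locus with
    probability ``p_background``. Open-chromatin peaks cover every active
    (activated or housekeeping) locus; states label active loci
    promoter-like and silent repeat loci repressive.
    """
    genome = genome or plan.genome
    rng = np.random.default_rng(plan.rng().integers(2 ** 31) + 2)
    loci = truth.loci
    active = loci[loci["kind"].isin(["activated", "housekeeping"])]
    activated = loci[loci["kind"] == "activated"]

    def _tf_peak(row, offset_lo, offset_hi):
        off = int(rng.integers(offset_lo, offset_hi))
        mid = row.tss + off if row.strand == "+" else row.tss - off
        return (row.chrom, mid - 100, mid + 100, ".", mid)

    tf_sets, tf_targets = {}, {}
    clique_tfs = [f"TFC{i + 1}" for i in range(plan.n_clique_tfs)]
    background_tfs = [f"TFB{i + 1}" for i in range(plan.n_background_tfs)]
    for tf in clique_tfs:
        rows, targets = [], set()
        for lid, row in activated.iterrows():
            if rng.random() < plan.p_clique:
                rows.append(_tf_peak(row, -100, 0))
                targets.add(lid)
        tf_sets[tf] = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                  "strand", "summit"])
        tf_targets[tf] = targets
    for tf in background_tfs:
        rows, targets = [], set()
        for lid, row in loci.iterrows():
            if rng.random() < plan.p_background:
                rows.append(_tf_peak(row, -500, 500))
                targets.add(lid)
        tf_sets[tf] = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                  "strand", "summit"])
        tf_targets[tf] = targets

    open_rows = [(row.chrom, row.tss - 300, row.tss + 300, ".", row.tss)
                 for _, row in active.iterrows()]
    open_chromatin = pd.DataFrame(open_rows, columns=["chrom", "start", "end",
                                                      "strand", "summit"])

    state_rows = [(row.chrom, max(row.tss - 500, 0), row.tss + 500,
                   "Active_Promoter") for _, row in active.iterrows()]
    states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"])

    # cell-line CTSS: expresses activated + housekeeping loci at their mu
    cell_rows = []
    for _, row in active.iterrows():
        total = int(rng.poisson(max(row.mu, 1.0)))
        if total == 0:
            continue
        window = rng.multinomial(total, TAG_WINDOW_WEIGHTS)
        offs = np.arange(-2, 3)
        if row.strand == "-":
            offs = offs[::-1]
        for off, c in zip(offs, window):
            if c > 0:
                cell_rows.append((row.chrom, row.tss + off, row.strand, int(c)))
    cell_ctss = (pd.DataFrame(cell_rows, columns=CTSS_COLUMNS)
                 .groupby(["chrom", "pos", "strand"], as_index=False)["count"]
                 .sum()
                 .sort_values(["chrom", "pos", "strand"], kind="mergesort")
                 .reset_index(drop=True))

    truth.tf_targets = tf_targets
    truth.clique_tfs = clique_tfs
    return tf_sets, open_chromatin, states, cell_ctss


def add_silent_states(states: pd.DataFrame, repeats: pd.DataFrame,
                      loci: pd.DataFrame) -> pd.DataFrame:
    """Label repeat copies without planted promoters as repressive chromatin."""
    used = set(loci["element_id"].dropna().astype(int))
    silent = repeats[~repeats["element_id"].isin(used)]
    extra = pd.DataFrame({
        "chrom": silent["chrom"], "start": silent["start"],
        "end": silent["end"], "state": "Heterochrom"})
    return (pd.concat([states, extra], ignore_index=True)
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def simulate_counts(n_peaks: int, n_a: int, n_b: int, mu, fold: float,
                    phi: float, rng,
                    libsize_factor_sd: float = 0.0) -> tuple:
    """Matrix-level NB count simulation for test/calibration studies.

    Group A samples have mean mu*fold, group B mean mu; returns
    (counts DataFrame, library_sizes Series) with nominal library size 1e6.
    """
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_peaks,))
    cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    factors = np.exp(rng.normal(0.0, libsize_factor_sd, size=n_a + n_b))
    data = np.empty((n_peaks, n_a + n_b), dtype=np.int64)
    for j in range(n_a + n_b):
        m = mu * (fold if j < n_a else 1.0) * factors[j]
        data[:, j] = _nb_draw(rng, m, phi)
    counts = pd.DataFrame(data, columns=cols,
                          index=[f"pk{i:05d}" for i in range(n_peaks)])
    libs = pd.Series(1e6 * factors, index=cols, name="library_size")
    return counts, libs
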