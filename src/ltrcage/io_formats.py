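"""Readers and writers for every external format the pipeline touches.

All internal coordinates are 0-based half-open. Formats that ship 1-based
inclusive coordinates (RepeatMasker ``.out``, GTF) are converted on read and
back on write. Minus-strand CTSS positions denote the 5' base itself.

Tabular data is held in pandas DataFrames; small structured records (genes,
genome layout) are plain dataclasses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]
REPEAT_COLUMNS = ["element_id", "chrom", "start", "end", "strand",
                  "subfamily", "family", "is_internal"]

FAMILIES = ("LTR", "LINE", "SINE", "SVA", "Other")


class FormatError(ValueError):
    """A malformed line in an external file; message names the line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths of the working assembly."""

    chrom_names: tuple
    chrom_lengths: tuple

    def __post_init__(self):
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom_names, "length": self.chrom_lengths})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeLayout":
        return cls(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))


@dataclass
class GeneModel:
    """A protein-coding (or other) gene: TSS plus exon intervals, half-open."""

    gene_id: str
    chrom: str
    strand: str
    tss_pos: int
    exons: list  # list of (start, end) half-open
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.exons:
            five_prime = (min(s for s, _ in self.exons) if self.strand == "+"
                          else max(e for _, e in self.exons) - 1)
            if self.tss_pos != five_prime:
                raise ValueError(
                    f"{self.gene_id}: tss_pos {self.tss_pos} is not the 5'-most "
                    f"exon boundary ({five_prime})")


# ---------------------------------------------------------------------------
# CTSS BED6
# ---------------------------------------------------------------------------

def read_ctss(path: str | Path) -> pd.DataFrame:
    """Read a ctss.bed file (BED6; the score column holds the tag count).

    Records at the same (chrom, pos, strand) are summed; the result is sorted
    by (chrom, pos, strand) and counts are preserved exactly.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 columns, "
                                  f"got {len(parts)}")
            try:
                pos = int(parts[1])
                end = int(parts[2])
                count = int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if count < 0:
                raise FormatError(f"{path}: line {lineno}: negative count {count}")
            if end != pos + 1:
                raise FormatError(f"{path}: line {lineno}: CTSS records must be "
                                  f"single-base (end == start + 1)")
            if parts[5] not in STRANDS:
                raise FormatError(f"{path}: line {lineno}: bad strand {parts[5]!r}")
            if count >= 1:
                rows.append((parts[0], pos, parts[5], count))
    df = pd.DataFrame(rows, columns=CTSS_COLUMNS)
    if df.empty:
        return df
    df = (df.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
            .sort_values(["chrom", "pos", "strand"], kind="mergesort")
            .reset_index(drop=True))
    return df


def write_ctss(ctss: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in ctss.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t.\t"
                     f"{int(row.count)}\t{row.strand}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out and BED6 fallback
# ---------------------------------------------------------------------------

def classify_repeat_family(class_family: str) -> str:
    """Map a RepeatMasker class/family string to {LTR, LINE, SINE, SVA, Other}."""
    head = class_family.split("/")[0].strip()
    if head in ("LTR", "LINE", "SINE", "SVA"):
        return head
    if "SVA" in class_family:
        return "SVA"
    return "Other"


def read_repeatmasker_out(path: str | Path) -> pd.DataFrame:
    """Read RepeatMasker ``.out`` (3 header lines, 1-based inclusive, C = minus).

    Unknown class strings map to family ``Other`` with a logged warning;
    subfamilies ending in ``-int`` are flagged ``is_internal``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 11:
                raise FormatError(f"{path}: line {lineno}: expected >=11 columns")
            chrom, begin, end, strand_raw = parts[4], parts[5], parts[6], parts[8]
            name, class_family = parts[9], parts[10]
            try:
                start0 = int(begin) - 1
                end0 = int(end)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if start0 >= end0:
                raise FormatError(f"{path}: line {lineno}: empty interval")
            if strand_raw == "C":
                strand = "-"
            elif strand_raw == "+":
                strand = "+"
            else:
                raise FormatError(f"{path}: line {lineno}: bad strand {strand_raw!r}")
            family = classify_repeat_family(class_family)
            if family == "Other" and class_family.split("/")[0] not in (
                    "DNA", "Simple_repeat", "Low_complexity", "Satellite",
                    "RC", "rRNA", "tRNA", "snRNA", "srpRNA", "scRNA", "Other",
                    "Unknown", "RNA"):
                logger.warning("%s: line %d: unknown repeat class %r -> Other",
                               path, lineno, class_family)
            rows.append((chrom, start0, end0, strand, name, family,
                         name.endswith("-int")))
    df = pd.DataFrame(rows, columns=REPEAT_COLUMNS[1:])
    df.insert(0, "element_id", np.arange(len(df)))
    return df


def read_repeats_bed(path: str | Path) -> pd.DataFrame:
    """BED6 fallback for repeats; the name column is ``subfamily:family``."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 columns")
            name = parts[3]
            if ":" in name:
                subfamily, family = name.split(":", 1)
            else:
                subfamily, family = name, "Other"
            if family not in FAMILIES:
                logger.warning("%s: line %d: unknown family %r -> Other",
                               path, lineno, family)
                family = "Other"
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[5],
                         subfamily, family, subfamily.endswith("-int")))
    df = pd.DataFrame(rows, columns=REPEAT_COLUMNS[1:])
    df.insert(0, "element_id", np.arange(len(df)))
    return df


def write_repeats_bed(repeats: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in repeats.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                     f"{row.subfamily}:{row.family}\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# GTF-lite gene annotation
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(raw: str) -> dict:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(path: str | Path) -> list:
    """Read a GTF-lite annotation (exon lines with gene_id / gene_biotype).

    Returns GeneModel objects; the TSS is the 5'-most exon boundary on the
    gene strand. GTF is 1-based inclusive and converted to half-open here.
    """
    exons: dict = {}
    meta: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attr_raw = parts
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr_raw)
            if "gene_id" not in attrs:
                raise FormatError(f"{path}: line {lineno}: missing gene_id")
            gid = attrs["gene_id"]
            exons.setdefault(gid, []).append((int(start1) - 1, int(end1)))
            meta.setdefault(gid, (chrom, strand,
                                  attrs.get("gene_biotype", "other")))
    genes = []
    for gid, ex in exons.items():
        chrom, strand, biotype = meta[gid]
        ex = sorted(ex)
        tss = ex[0][0] if strand == "+" else max(e for _, e in ex) - 1
        genes.append(GeneModel(gid, chrom, strand, tss, ex, biotype))
    genes.sort(key=lambda g: (g.chrom, g.tss_pos, g.gene_id))
    return genes


def write_gtf_genes(genes: list, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for start, end in g.exons:
                fh.write(f"{g.chrom}\tltrcage\texon\t{start + 1}\t{end}\t.\t"
                         f"{g.strand}\t.\t"
                         f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";\n')


# ---------------------------------------------------------------------------
# narrowPeak / chromatin-state BED
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read a 10-column narrowPeak file; resolves the summit offset.

    A summit offset of -1 resolves to the interval midpoint; an offset not
    inside the interval is an error; files without exactly 10 columns are
    rejected as the wrong dialect.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 10:
                raise FormatError(f"{path}: line {lineno}: narrowPeak requires "
                                  f"10 columns, got {len(parts)}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if parts[5] in STRANDS else "."
            offset = int(parts[9])
            if offset == -1:
                summit = (start + end) // 2
            else:
                if offset >= end - start:
                    raise FormatError(f"{path}: line {lineno}: summit offset "
                                      f"{offset} outside interval")
                summit = start + offset
            rows.append((chrom, start, end, strand, summit))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "summit"])


def write_narrowpeak(peaks: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in peaks.itertuples(index=False):
            offset = int(row.summit) - int(row.start)
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t0\t"
                     f"{getattr(row, 'strand', '.')}\t0\t-1\t-1\t{offset}\n")


def read_state_bed(path: str | Path) -> pd.DataFrame:
    """Chromatin-state BED: the name column carries the state label."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: expected >=4 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def write_state_bed(states: pd.DataFrame, path: str | Path) -> None:
    states.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Sample sheet and matrices
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """TSV sample sheet indexed by sample_id.

    Required columns: sample_id, group, library_size; optional pair_id; every
    further column is treated as a clinical covariate.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group", "library_size"):
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet missing column {col!r}")
    if (df["library_size"] <= 0).any():
        raise FormatError(f"{path}: library_size must be positive")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    df = df.set_index("sample_id")
    if "pair_id" in df.columns:
        pairs = df["pair_id"].dropna()
        grouped = pairs.groupby(pairs).size()
        if (grouped > 2).any():
            raise FormatError(f"{path}: pair_id shared by more than two samples")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=True, index_label="sample_id")


def covariate_columns(sheet: pd.DataFrame) -> list:
    reserved = {"group", "pair_id", "library_size", "tier"}
    return [c for c in sheet.columns if c not in reserved]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Peak x sample TSV matrix (first column = peak id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="peak_id")
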