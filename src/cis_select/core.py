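"""Core domain types for insertional-mutagenesis screen analysis.

Coordinate conventions
----------------------
Point loci (insertion sites, TSSs, CIS peaks) are 1-based base-pair
positions.  Intervals (regions, pseudo-kernels, BED records) are 0-based
half-open internally; conversion to/from BED happens only at I/O
boundaries.  CIS extents are 1-based inclusive, spanning the minimum and
maximum member coordinates.

Insertion cohorts are held as pandas DataFrames with the column schema
given by :data:`COHORT_COLUMNS`; :class:`InsertionSite` is the record-level
view used for construction and round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

#: column schema of a cohort DataFrame
COHORT_COLUMNS = ("chrom", "pos", "strand", "sample_id", "genotype", "reads")


class ValidationError(ValueError):
    """An input violates a domain invariant."""


@dataclass(frozen=True)
class InsertionSite:
    """One unique retroviral insertion site (RIS).

    Attributes
    ----------
    chrom : chromosome name
    pos : 1-based base-pair position of the provirus-host junction
    strand : '+' or '-' relative to the reference plus strand
    sample_id : tumour identifier
    genotype : cohort label (free text; empty string if unused)
    reads : supporting read count (>= 1)
    """

    chrom: str
    pos: int
    strand: str
    sample_id: str
    genotype: str = ""
    reads: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.reads < 1:
            raise ValidationError(f"reads must be >= 1, got {self.reads}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")


def sites_to_frame(sites: Iterable[InsertionSite]) -> pd.DataFrame:
    """Pack InsertionSite records into the cohort DataFrame schema."""
    rows = [(s.chrom, s.pos, s.strand, s.sample_id, s.genotype, s.reads) for s in sites]
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return coerce_cohort(df)


def frame_to_sites(cohort: pd.DataFrame) -> list[InsertionSite]:
    """Unpack a cohort DataFrame into InsertionSite records."""
    return [
        InsertionSite(r.chrom, int(r.pos), r.strand, r.sample_id, r.genotype, int(r.reads))
        for r in cohort.itertuples(index=False)
    ]


def coerce_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes of a cohort frame and validate invariants."""
    df = df.copy()
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"cohort frame missing column {col!r}")
    df["pos"] = df["pos"].astype(np.int64)
    df["reads"] = df["reads"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    df["genotype"] = df["genotype"].fillna("").astype(str)
    if len(df):
        if int(df["pos"].min()) < 1:
            raise ValidationError("cohort contains pos < 1")
        if int(df["reads"].min()) < 1:
            raise ValidationError("cohort contains reads < 1")
        bad = ~df["strand"].isin(STRANDS)
        if bad.any():
            raise ValidationError(f"invalid strand values: {sorted(df.loc[bad, 'strand'].unique())}")
    return df[list(COHORT_COLUMNS)].reset_index(drop=True)


def sort_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Reproducible (chrom, pos, strand, sample) ordering."""
    return df.sort_values(
        ["chrom", "pos", "strand", "sample_id"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class GenomeModel:
    """Chromosome lengths plus optional TSS and gene-interval annotation.

    ``tss_table`` columns: gene_id, chrom, tss_pos (1-based), strand.
    ``gene_intervals`` columns: gene_id, chrom, start, end (0-based half-open).
    """

    chrom_lengths: dict[str, int]
    tss_table: Optional[pd.DataFrame] = None
    gene_intervals: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has non-positive length {length}")
        if self.tss_table is not None and len(self.tss_table):
            t = self.tss_table
            for _, row in t.iterrows():
                L = self.chrom_lengths.get(row["chrom"])
                if L is None:
                    raise ValidationError(f"TSS on unknown chromosome {row['chrom']!r}")
                if not (1 <= row["tss_pos"] <= L):
                    raise ValidationError(
                        f"TSS of {row['gene_id']} at {row['tss_pos']} outside {row['chrom']} (len {L})"
                    )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def contains(self, chrom: str, pos: int) -> bool:
        L = self.chrom_lengths.get(chrom)
        return L is not None and 1 <= pos <= L

    def uniform_positions(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw n positions uniformly over the genome (chromosome prob ∝ length).

        Returns a frame with columns chrom, pos (1-based).
        """
        chroms = np.array(self.chroms)
        lengths = np.array([self.chrom_lengths[c] for c in chroms], dtype=float)
        which = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
        pos = (rng.random(n) * lengths[which]).astype(np.int64) + 1
        return pd.DataFrame({"chrom": chroms[which], "pos": pos})


@dataclass
class RegionSet:
    """A named set of genomic intervals (0-based half-open)."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        df = self.intervals
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValidationError(f"region set {self.name!r} has start >= end")
        self.intervals = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    def total_bp(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


@dataclass
class CIS:
    """A common insertion site: a significant cluster of insertions.

    ``start``/``end`` are the 1-based inclusive minimum/maximum member
    coordinates; ``peak_pos``/``peak_height``/``scale`` come from the
    smallest kernel scale at which the cluster is significant.
    ``member_index`` holds integer row positions into the cohort frame the
    CIS was called on.
    """

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_height: float
    scale: float
    member_index: np.ndarray
    n_insertions: int = 0
    n_samples: int = 0
    #: scales (bp) at which this cluster reached significance
    supporting_scales: tuple = ()
    #: extent of the merged cross-scale candidate group (1-based inclusive)
    envelope: "Optional[tuple[int, int]]" = None
    #: union of member rows over all supporting scales
    all_member_index: "Optional[np.ndarray]" = None

    def __post_init__(self) -> None:
        self.member_index = np.asarray(self.member_index, dtype=np.int64)
        if self.n_insertions == 0:
            self.n_insertions = int(len(self.member_index))
        if not (self.start <= self.peak_pos <= self.end):
            raise ValidationError(
                f"CIS peak {self.peak_pos} outside extent [{self.start}, {self.end}]"
            )
        if self.n_insertions < 2:
            raise ValidationError("a CIS needs >= 2 member insertions")

    def members(self, cohort: pd.DataFrame) -> pd.DataFrame:
        return cohort.iloc[self.member_index]

    @property
    def width(self) -> int:
        return self.end - self.start + 1


# UCSC mm9 chromosome sizes (autosomes + X + Y), used for mm9-scale work.
MM9_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 197195432,
    "chr2": 181748087,
    "chr3": 159599783,
    "chr4": 155630120,
    "chr5": 152537259,
    "chr6": 149517037,
    "chr7": 152524553,
    "chr8": 131738871,
    "chr9": 124076172,
    "chr10": 129993255,
    "chr11": 121843856,
    "chr12": 121257530,
    "chr13": 120284312,
    "chr14": 125194864,
    "chr15": 103494974,
    "chr16": 98319150,
    "chr17": 95272651,
    "chr18": 90772031,
    "chr19": 61342430,
    "chrX": 166650296,
    "chrY": 15902555,
}


def mm9_like_genome(
    n_genes: int = 0,
    seed: Optional[int] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> GenomeModel:
    """A mouse-genome-scale GenomeModel, optionally with synthetic genes.

    When ``n_genes`` > 0, gene TSSs are placed uniformly over the genome
    (chromosome probability proportional to length) with fair-coin strands,
    and each gene is given a 20 kb synthetic gene body downstream of its
    TSS.  Synthetic annotation only: positions do not correspond to real
    mm9 genes.
    """
    lengths = dict(chrom_lengths) if chrom_lengths is not None else dict(MM9_CHROM_LENGTHS)
    tss = None
    genes = None
    if n_genes:
        rng = np.random.default_rng(seed)
        g = GenomeModel(lengths)
        placed = g.uniform_positions(n_genes, rng)
        strands = np.where(rng.random(n_genes) < 0.5, FORWARD, REVERSE)
        gene_ids = [f"gene{idx:05d}" for idx in range(n_genes)]
        tss = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chrom": placed["chrom"],
                "tss_pos": placed["pos"],
                "strand": strands,
            }
        )
        body = 20_000
        chrom_len = placed["chrom"].map(lengths).to_numpy(np.int64)
        fwd = strands == FORWARD
        start = np.where(fwd, placed["pos"] - 1, placed["pos"] - body)
        end = np.where(fwd, placed["pos"] - 1 + body, placed["pos"])
        genes = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chrom": placed["chrom"],
                "start": np.clip(start, 0, chrom_len),
                "end": np.clip(end, 0, chrom_len),
            }
        )
    return GenomeModel(lengths, tss_table=tss, gene_intervals=genes)


def toy_genome(n_chroms: int = 1, length: int = 100_000_000) -> GenomeModel:
    """Small uniform genome for tests and examples."""
    return GenomeModel({f"chr{i + 1}": length for i in range(n_chroms)})
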