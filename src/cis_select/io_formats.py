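"""Reading and writing the interval formats the pipeline touches.

Insertion cohorts and region sets travel as BED6 / BED3; TSS annotation,
gene sets and CIS summaries as tab-separated tables.  All conversions
between BED's 0-based half-open convention and the internal 1-based point
convention happen here and nowhere else.  Outputs are reproducibly sorted
by (chrom, start).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    CIS,
    COHORT_COLUMNS,
    GenomeModel,
    RegionSet,
    STRANDS,
    ValidationError,
    coerce_cohort,
    sort_cohort,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed row in an input file; message names the line number."""


def _split_name(name: str, dialect: str) -> tuple[str, str]:
    """BED name field -> (sample_id, genotype).

    dialect 'sample': the whole name is the sample id.
    dialect 'sample_extra': 'sample|extra' with the extra token kept as the
    genotype/cohort label.
    """
    if dialect == "sample_extra" and "|" in name:
        sample, extra = name.split("|", 1)
        return sample, extra
    return name, ""


def read_ris_bed(
    path: PathLike,
    genome: GenomeModel,
    dialect: str = "sample_extra",
    ignore_unplaced: bool = False,
) -> pd.DataFrame:
    """Read mapped insertion sites from a BED6-like file into a cohort frame.

    Columns expected: chrom, start (0-based), end, name (sample id, or
    sample|genotype under the 'sample_extra' dialect), score (read count),
    strand.  BED start is converted to the 1-based junction position.
    Rows on chromosomes absent from ``genome`` raise unless
    ``ignore_unplaced`` (silent drops would corrupt genome-wide null
    calibration).
    """
    if dialect not in ("sample", "sample_extra"):
        raise ValueError(f"unknown BED name dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 tab-separated columns, got {len(fields)}")
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start = int(start_s)
                int(end_s)
                reads = int(float(score_s))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate or score ({exc})") from None
            if start < 0:
                raise ValidationError(f"{path}:{lineno}: negative BED start {start}")
            if strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            if reads < 1:
                raise ValidationError(f"{path}:{lineno}: read count must be >= 1, got {reads}")
            pos = start + 1  # BED 0-based start -> 1-based junction
            if chrom not in genome.chrom_lengths:
                if ignore_unplaced:
                    continue
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not genome.contains(chrom, pos):
                raise ValidationError(f"{path}:{lineno}: position {pos} outside {chrom}")
            sample, genotype = _split_name(name, dialect)
            rows.append((chrom, pos, strand, sample, genotype, reads))
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return coerce_cohort(df)


def write_ris_bed(cohort: pd.DataFrame, path: PathLike, dialect: str = "sample_extra") -> None:
    """Write a cohort frame as BED6 (inverse of :func:`read_ris_bed`)."""
    df = sort_cohort(coerce_cohort(cohort))
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            name = f"{r.sample_id}|{r.genotype}" if (dialect == "sample_extra" and r.genotype) else r.sample_id
            fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{name}\t{r.reads}\t{r.strand}\n")


CIS_TSV_COLUMNS = (
    "chrom",
    "start",
    "end",
    "peak_pos",
    "peak_height",
    "scale",
    "n_insertions",
    "n_samples",
)


def cis_table(cis_list: Sequence[CIS]) -> pd.DataFrame:
    """Summary frame of CIS calls, sorted by (chrom, start)."""
    rows = [
        (c.chrom, c.start, c.end, c.peak_pos, c.peak_height, c.scale, c.n_insertions, c.n_samples)
        for c in cis_list
    ]
    df = pd.DataFrame(rows, columns=list(CIS_TSV_COLUMNS))
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_cis_outputs(cis_list: Sequence[CIS], path_prefix: PathLike) -> tuple[Path, Path]:
    """Write CIS calls as <prefix>.bed (extents) and <prefix>.tsv (summary).

    BED extents are 0-based half-open: a 1-based inclusive extent
    [100, 200] becomes start=99, end=200.
    """
    prefix = Path(path_prefix)
    df = cis_table(cis_list)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    with open(bed_path, "w") as fh:
        for r in df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tCIS\t{r.n_insertions}\t.\n")
    df.to_csv(tsv_path, sep="\t", index=False)
    return bed_path, tsv_path


def read_cis_tsv(path: PathLike) -> pd.DataFrame:
    """Read back a CIS summary TSV written by :func:`write_cis_outputs`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CIS_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing CIS columns {sorted(missing)}")
    return df


def read_regions_bed(path: PathLike, name: Optional[str] = None) -> RegionSet:
    """Read a BED3+ file of genomic regions (kept 0-based half-open).

    Overlapping intervals are retained as-is; overlap is resolved by the
    consumers that need flattened coverage.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer interval bounds") from None
            rows.append((fields[0], start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return RegionSet(name or Path(path).stem, df)


def write_regions_bed(regions: RegionSet, path: PathLike) -> None:
    regions.intervals.sort_values(["chrom", "start"], kind="mergesort").to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tss_table(path: PathLike) -> pd.DataFrame:
    """Read a TSS annotation table: gene_id, chrom, tss_pos (1-based), strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["gene_id", "chrom", "tss_pos", "strand"],
        dtype={"gene_id": str, "chrom": str, "strand": str},
    )
    if len(df):
        if not df["strand"].isin(STRANDS).all():
            raise ParseError(f"{path}: gene strand column must be + or -")
        df["tss_pos"] = df["tss_pos"].astype(np.int64)
        if int(df["tss_pos"].min()) < 1:
            raise ValidationError(f"{path}: TSS positions must be >= 1")
    return df.reset_index(drop=True)


def write_tss_table(tss: pd.DataFrame, path: PathLike) -> None:
    tss[["gene_id", "chrom", "tss_pos", "strand"]].to_csv(path, sep="\t", header=False, index=False)


def read_genesets(path: PathLike) -> dict[str, list[str]]:
    """Read gene sets: one set per line, 'name<TAB>gene1<TAB>gene2...'.

    Duplicate genes within one set are deduplicated with a warning; an
    empty file yields an empty mapping.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: gene set line needs a name and >= 1 gene")
            name, genes = fields[0], fields[1:]
            seen: dict[str, None] = {}
            dupes = []
            for g in genes:
                if g in seen:
                    dupes.append(g)
                else:
                    seen[g] = None
            if dupes:
                warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r}: {sorted(set(dupes))}")
            sets[name] = list(seen)
    return sets
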