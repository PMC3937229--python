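"""Collapse mapped read starts into unique insertion sites and summarise clonality.

Reads from the same tumour whose genomic start positions fall within a
small gap of each other are treated as one integration event; the merged
site keeps the position of its deepest pile-up and the summed read count.
Clonally expanded insertions are flagged by a read-count threshold
(default 100 reads), the screen's operational definition of an expanded
tumour subclone.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CIS, GenomeModel, ValidationError, coerce_cohort, sort_cohort


def merge_sites(
    raw_sites: pd.DataFrame,
    max_gap: int = 3,
    ignore_strand: bool = False,
) -> pd.DataFrame:
    """Merge read starts within ``max_gap`` bp (same sample) into unique RISs.

    Within each (sample, chrom, strand) group — or (sample, chrom) when
    ``ignore_strand`` — positions are chained by single linkage: a run of
    sites whose consecutive gaps are all <= ``max_gap`` becomes one RIS
    (so 100, 103, 106 merge at the default gap even though the end points
    are 6 apart).  The merged RIS takes the summed read count and the
    position/strand of the member with the highest read count (ties:
    smallest position).  Idempotent, order-independent, read-conserving.
    """
    if max_gap < 0:
        raise ValidationError(f"max_gap must be >= 0, got {max_gap}")
    df = coerce_cohort(raw_sites)
    if not len(df):
        return df
    keys = ["sample_id", "chrom"] + ([] if ignore_strand else ["strand"])
    out = []
    for _, grp in df.sort_values("pos", kind="mergesort").groupby(keys, sort=False):
        pos = grp["pos"].to_numpy()
        reads = grp["reads"].to_numpy()
        # chain id increments where the gap to the previous site exceeds max_gap
        chain = np.concatenate([[0], np.cumsum(np.diff(pos) > max_gap)])
        for cid in np.unique(chain):
            m = chain == cid
            sub = grp.iloc[np.flatnonzero(m)]
            r = sub["reads"].to_numpy()
            p = sub["pos"].to_numpy()
            best = np.flatnonzero(r == r.max())
            rep = best[np.argmin(p[best])]  # ties -> smallest position
            row = sub.iloc[rep]
            out.append(
                (row["chrom"], int(p[rep]), row["strand"], row["sample_id"], row["genotype"], int(r.sum()))
            )
    merged = pd.DataFrame(out, columns=list(df.columns))
    return sort_cohort(coerce_cohort(merged))


def flag_expanded(cohort: pd.DataFrame, threshold: int = 100) -> tuple[pd.DataFrame, pd.Series]:
    """Select clonally expanded RISs: reads >= ``threshold`` (inclusive).

    Returns the expanded subset (index preserved from ``cohort``) and the
    per-sample count of expanded RISs (zero-filled over all samples).
    """
    if threshold < 1:
        raise ValidationError(f"threshold must be >= 1, got {threshold}")
    expanded = cohort[cohort["reads"] >= threshold]
    per_sample = (
        expanded.groupby("sample_id").size().reindex(sorted(cohort["sample_id"].unique()), fill_value=0)
    )
    return expanded, per_sample


def reads_per_ris_summary(cis: CIS, cohort: pd.DataFrame) -> tuple[int, int, float]:
    """(n_insertions, n_samples, mean reads per RIS) over a CIS's members."""
    members = cis.members(cohort)
    if not len(members):
        raise ValidationError("CIS has no members")
    return (
        int(len(members)),
        int(members["sample_id"].nunique()),
        float(members["reads"].mean()),
    )


def _merged_gene_intervals(genome: GenomeModel) -> dict[str, np.ndarray]:
    """Per-chromosome merged gene intervals as (n, 2) arrays, 0-based half-open."""
    merged: dict[str, np.ndarray] = {}
    for chrom, grp in genome.gene_intervals.groupby("chrom"):
        iv = grp[["start", "end"]].sort_values("start").to_numpy(np.int64)
        keep = []
        cur_s, cur_e = iv[0]
        for s, e in iv[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                keep.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        keep.append((cur_s, cur_e))
        merged[chrom] = np.array(keep, dtype=np.int64)
    return merged


def classify_passengers(
    cohort: pd.DataFrame,
    cis_list: Sequence[CIS],
    genome: GenomeModel,
    max_gene_distance: int = 100_000,
) -> pd.Series:
    """Label each RIS as cis_member / near_gene / passenger.

    An RIS belonging to any called CIS is a ``cis_member``; otherwise it
    is ``near_gene`` if within ``max_gene_distance`` bp (inclusive) of any
    annotated gene interval, else a ``passenger`` — the operational
    reading of an isolated insertion far from any target gene.
    """
    if genome.gene_intervals is None or not len(genome.gene_intervals):
        raise ValidationError("classify_passengers requires gene_intervals annotation")
    labels = np.full(len(cohort), "passenger", dtype=object)
    in_cis = np.zeros(len(cohort), dtype=bool)
    for c in cis_list:
        in_cis[c.member_index] = True

    intervals = _merged_gene_intervals(genome)
    pos = cohort["pos"].to_numpy(np.int64)
    for chrom, iv in intervals.items():
        rows = np.flatnonzero((cohort["chrom"] == chrom).to_numpy())
        if not len(rows):
            continue
        p = pos[rows]
        starts1 = iv[:, 0] + 1  # 1-based inclusive interval starts
        ends1 = iv[:, 1]
        idx = np.searchsorted(starts1, p, side="right")
        dist = np.full(len(p), np.iinfo(np.int64).max, dtype=np.int64)
        has_left = idx > 0
        li = np.clip(idx - 1, 0, len(iv) - 1)
        inside = has_left & (p <= ends1[li])
        dist[inside] = 0
        left_gap = np.where(has_left & ~inside, p - ends1[li], np.iinfo(np.int64).max)
        has_right = idx < len(iv)
        ri = np.clip(idx, 0, len(iv) - 1)
        right_gap = np.where(has_right, starts1[ri] - p, np.iinfo(np.int64).max)
        dist = np.minimum(dist, np.minimum(left_gap, right_gap))
        near = rows[dist <= max_gene_distance]
        labels[near] = "near_gene"
    labels[in_cis] = "cis_member"
    return pd.Series(labels, index=cohort.index, name="role")
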