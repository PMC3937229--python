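"""Statistical evidence of post-integration selection.

Orientation bias per CIS (one-tailed Fisher exact against all remaining
sites, Benjamini-Hochberg corrected), signed insertion-to-TSS distance
profiles, CIS-set overlap, genomic-bin contingency enrichment, genotype
comparisons (Fisher presence tests, Mann-Whitney read-abundance tests)
and hypergeometric gene-set enrichment with top-k target removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import CIS, GenomeModel, RegionSet, ValidationError


@dataclass
class OrientationTestResult:
    """Strand-orientation skew of one CIS versus all remaining sites."""

    cis: CIS
    fwd_in: int
    rev_in: int
    fwd_out: int
    rev_out: int
    bias: float  # majority fraction among members, in [0.5, 1]
    p: float
    q: float = np.nan


def orientation_test(cis: CIS, all_ris: pd.DataFrame) -> OrientationTestResult:
    """One-tailed Fisher exact test for orientation bias of a CIS.

    The 2x2 table compares the CIS members' strand counts with the strand
    counts of every RIS not in the CIS; the tested tail is enrichment of
    the CIS's majority orientation.  A forward/reverse tie within the CIS
    gives p = 1 by definition.
    """
    members = cis.members(all_ris)
    if not len(members):
        raise ValidationError("orientation test on CIS with no members")
    strands = members["strand"].to_numpy()
    fwd_in = int((strands == "+").sum())
    rev_in = int(len(strands) - fwd_in)
    out_mask = np.ones(len(all_ris), dtype=bool)
    out_mask[cis.member_index] = False
    out_strands = all_ris["strand"].to_numpy()[out_mask]
    fwd_out = int((out_strands == "+").sum())
    rev_out = int(len(out_strands) - fwd_out)
    bias = max(fwd_in, rev_in) / (fwd_in + rev_in)
    if fwd_in == rev_in:
        p = 1.0
    else:
        if fwd_in > rev_in:
            table = [[fwd_in, rev_in], [fwd_out, rev_out]]
        else:
            table = [[rev_in, fwd_in], [rev_out, fwd_out]]
        _, p = stats.fisher_exact(table, alternative="greater")
    return OrientationTestResult(cis, fwd_in, rev_in, fwd_out, rev_out, bias, float(p))


def orientation_pvalues_vectorised(
    fwd_in: np.ndarray, n_in: np.ndarray, fwd_total: int, n_total: int
) -> np.ndarray:
    """Batch form of :func:`orientation_test`'s p-value.

    The one-tailed Fisher p of [[maj_in, min_in], [maj_out, min_out]] is
    the hypergeometric tail P(X >= maj_in) with population ``n_total``,
    ``maj_total`` successes and ``n_in`` draws; ties give p = 1.  Agrees
    with :func:`orientation_test` exactly (tested) and exists for the
    large batteries where per-cluster scipy calls are too slow.
    """
    fwd_in = np.asarray(fwd_in, dtype=np.int64)
    n_in = np.asarray(n_in, dtype=np.int64)
    rev_in = n_in - fwd_in
    maj_in = np.maximum(fwd_in, rev_in)
    maj_total = np.where(fwd_in >= rev_in, fwd_total, n_total - fwd_total)
    p = stats.hypergeom.sf(maj_in - 1, n_total, maj_total, n_in)
    return np.where(fwd_in == rev_in, 1.0, p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, q_i = min_{j>=i} p_(j) m/j."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def orientation_test_all(
    cis_list: Sequence[CIS], all_ris: pd.DataFrame
) -> list[OrientationTestResult]:
    """Orientation tests for every CIS, with BH-adjusted q filled in."""
    results = [orientation_test(c, all_ris) for c in cis_list]
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def biased_cis_set(
    results: Sequence[OrientationTestResult], q_cut: float = 0.05
) -> list[OrientationTestResult]:
    """CISs with BH-adjusted q strictly below ``q_cut`` (the 'biased CIS' set)."""
    return [r for r in results if r.q < q_cut]


def orientation_table(results: Sequence[OrientationTestResult]) -> pd.DataFrame:
    rows = [
        (
            r.cis.chrom,
            r.cis.start,
            r.cis.end,
            r.cis.n_insertions,
            r.fwd_in,
            r.rev_in,
            r.bias,
            r.p,
            r.q,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_insertions", "fwd", "rev", "bias", "p", "q"],
    )


def tss_distance_profile(
    ris_subset: pd.DataFrame,
    genome: GenomeModel,
    bins: Union[int, Sequence[float]] = 50,
) -> tuple[pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Signed distance of each RIS to its nearest TSS, plus a histogram.

    Distance is ris.pos - tss_pos with the sign flipped for minus-strand
    genes, so negative is always upstream of the gene.  Nearest is by
    absolute distance; ties go to the lexicographically smaller gene_id.
    An RIS on a chromosome without any TSS gets NaN distance and
    no_tss_on_chrom = True.
    """
    if genome.tss_table is None or not len(genome.tss_table):
        raise ValidationError("tss_distance_profile requires a TSS table")
    tss = genome.tss_table.sort_values(["chrom", "tss_pos", "gene_id"], kind="mergesort")
    by_chrom = {
        chrom: (
            grp["tss_pos"].to_numpy(np.int64),
            grp["gene_id"].to_numpy(object),
            grp["strand"].to_numpy(object),
        )
        for chrom, grp in tss.groupby("chrom")
    }
    n = len(ris_subset)
    dist = np.full(n, np.nan)
    gene = np.full(n, None, dtype=object)
    flagged = np.zeros(n, dtype=bool)
    pos_all = ris_subset["pos"].to_numpy(np.int64)
    chrom_all = ris_subset["chrom"].to_numpy()
    for chrom in np.unique(chrom_all):
        rows = np.flatnonzero(chrom_all == chrom)
        if chrom not in by_chrom:
            flagged[rows] = True
            continue
        tpos, tgene, tstrand = by_chrom[chrom]
        p = pos_all[rows]
        idx = np.searchsorted(tpos, p)
        for r, pi, ii in zip(rows, p, idx):
            # candidates: nearest TSS on each side, plus equal-position ties
            best_d = None
            best_gene = None
            best_signed = None
            for k in range(max(ii - 1, 0), min(ii + 1, len(tpos) - 1) + 1):
                d = abs(int(pi) - int(tpos[k]))
                # scan outward over equal-distance ties at the same coordinate
                if best_d is None or d < best_d or (d == best_d and tgene[k] < best_gene):
                    best_d = d
                    best_gene = tgene[k]
                    raw = int(pi) - int(tpos[k])
                    best_signed = raw if tstrand[k] == "+" else -raw
            dist[r] = best_signed
            gene[r] = best_gene
    df = pd.DataFrame(
        {
            "chrom": chrom_all,
            "pos": pos_all,
            "nearest_gene": gene,
            "distance": dist,
            "no_tss_on_chrom": flagged,
        },
        index=ris_subset.index,
    )
    valid = dist[~np.isnan(dist)]
    hist = np.histogram(valid, bins=bins) if len(valid) else (np.array([]), np.array([]))
    return df, hist


def cis_overlap(
    set_a: Sequence[CIS], set_b: Sequence[CIS]
) -> tuple[list[tuple[int, int]], int]:
    """Pairs (i, j) of CISs whose 1-based inclusive extents share >= 1 nt.

    Returns the overlapping index pairs and the number of A-CISs with at
    least one partner in B.
    """
    trees: dict[str, IntervalTree] = {}
    for j, b in enumerate(set_b):
        # half-open tree coordinates: inclusive [start, end] -> [start, end + 1)
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end + 1, j)
    pairs: list[tuple[int, int]] = []
    hit_a = set()
    for i, a in enumerate(set_a):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(a.start, a.end + 1), key=lambda v: v.data):
            pairs.append((i, iv.data))
            hit_a.add(i)
    return pairs, len(hit_a)


@dataclass
class BinEnrichmentResult:
    """One-sided Fisher enrichment of CIS peaks in region-overlapping bins."""

    bin_size: int
    total_bins: int
    region_bins: int
    cis_total: int
    cis_in_region: int
    p: float


def bin_enrichment_from_counts(
    cis_in_region: int, cis_total: int, region_bins: int, total_bins: int, bin_size: int = 30_000
) -> BinEnrichmentResult:
    """Fisher enrichment directly from printed counts."""
    if cis_in_region > cis_total or region_bins > total_bins:
        raise ValidationError("inconsistent contingency counts")
    cis_out = cis_total - cis_in_region
    table = [
        [cis_in_region, cis_out],
        [region_bins - cis_in_region, (total_bins - region_bins) - cis_out],
    ]
    if table[1][0] < 0 or table[1][1] < 0:
        raise ValidationError("more CISs than bins in a stratum; use a larger bin count")
    _, p = stats.fisher_exact(table, alternative="greater")
    return BinEnrichmentResult(bin_size, total_bins, region_bins, cis_total, cis_in_region, float(p))


def bin_enrichment(
    cis_list: Sequence[CIS],
    regions: RegionSet,
    genome: GenomeModel,
    bin_size: int = 30_000,
    by: str = "peak",
) -> BinEnrichmentResult:
    """Tile the genome into fixed bins and test CIS co-location with regions.

    Each chromosome contributes ceil(length / bin_size) bins; a bin is a
    region-bin if it intersects any region interval.  A CIS falls in a
    region-bin if the bin containing its peak is one (``by='peak'``,
    default) or if any bin overlapping its extent is one (``by='extent'``).
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    if by not in ("peak", "extent"):
        raise ValueError(f"unknown assignment mode {by!r}")
    region_bin_ids: set[tuple[str, int]] = set()
    total_bins = 0
    offsets: dict[str, int] = {}
    for chrom, L in genome.chrom_lengths.items():
        offsets[chrom] = total_bins
        total_bins += -(-L // bin_size)
    for r in regions.intervals.itertuples(index=False):
        L = genome.chrom_lengths.get(r.chrom)
        if L is None or r.end > L:
            raise ValidationError(f"region {r.chrom}:{r.start}-{r.end} outside genome")
        first = r.start // bin_size
        last = (r.end - 1) // bin_size
        for b in range(first, last + 1):
            region_bin_ids.add((r.chrom, b))
    cis_in = 0
    for c in cis_list:
        if by == "peak":
            hit = (c.chrom, (c.peak_pos - 1) // bin_size) in region_bin_ids
        else:
            first = (c.start - 1) // bin_size
            last = (c.end - 1) // bin_size
            hit = any((c.chrom, b) in region_bin_ids for b in range(first, last + 1))
        cis_in += bool(hit)
    return bin_enrichment_from_counts(
        cis_in, len(cis_list), len(region_bin_ids), total_bins, bin_size
    )


def _per_tumour_presence(
    cohort: pd.DataFrame,
    locus_extent: tuple[str, int, int],
    expanded_threshold: int,
) -> pd.DataFrame:
    chrom, start, end = locus_extent
    hit = (
        (cohort["chrom"] == chrom)
        & (cohort["pos"] >= start)
        & (cohort["pos"] <= end)
        & (cohort["reads"] >= expanded_threshold)
    )
    per = cohort.groupby(["genotype", "sample_id"]).apply(
        lambda g: bool(hit.loc[g.index].any()), include_groups=False
    )
    return per.rename("present").reset_index()


def genotype_presence_test(
    cohort: pd.DataFrame,
    locus_extent: tuple[str, int, int],
    focal_genotype: str,
    other_genotype: Optional[str] = None,
    expanded_threshold: int = 100,
) -> float:
    """Two-sided Fisher exact test of per-tumour locus occupancy by genotype.

    A tumour is locus-positive if it carries any expanded RIS (reads >=
    ``expanded_threshold``) within the 1-based inclusive ``locus_extent``
    (chrom, start, end).  The focal genotype is compared against one named
    genotype (pairwise mode) or against all remaining tumours pooled.
    """
    per = _per_tumour_presence(cohort, locus_extent, expanded_threshold)
    focal = per[per["genotype"] == focal_genotype]
    if other_genotype is None:
        rest = per[per["genotype"] != focal_genotype]
    else:
        rest = per[per["genotype"] == other_genotype]
    if not len(focal) or not len(rest):
        raise ValidationError("each compared group needs >= 1 tumour")
    table = [
        [int(focal["present"].sum()), int((~focal["present"]).sum())],
        [int(rest["present"].sum()), int((~rest["present"]).sum())],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def genotype_reads_test(
    cohort: pd.DataFrame,
    locus_extent: tuple[str, int, int],
    genotype_a: str,
    genotype_b: str,
    include_zeros: bool = False,
    exact_max_n: int = 8,
) -> float:
    """Two-sided Mann-Whitney U on per-tumour reads/RIS at a locus.

    The per-tumour statistic is the mean read count of its RISs inside the
    locus extent (0 for tumours without an insertion there;
    ``include_zeros`` keeps those tumours in the comparison).  Exact null
    distribution when both groups have <= ``exact_max_n`` tumours and no
    ties, normal approximation with tie correction otherwise.
    """
    chrom, start, end = locus_extent
    at_locus = cohort[
        (cohort["chrom"] == chrom) & (cohort["pos"] >= start) & (cohort["pos"] <= end)
    ]
    values = {}
    for geno in (genotype_a, genotype_b):
        samples = cohort.loc[cohort["genotype"] == geno, "sample_id"].unique()
        per = at_locus[at_locus["genotype"] == geno].groupby("sample_id")["reads"].mean()
        if include_zeros:
            v = per.reindex(samples, fill_value=0.0).to_numpy()
        else:
            v = per.to_numpy()
        values[geno] = v
    a, b = values[genotype_a], values[genotype_b]
    if not len(a) and not len(b):
        raise ValidationError("both groups empty at this locus")
    if not len(a) or not len(b):
        raise ValidationError("Mann-Whitney needs >= 1 value per group")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def geneset_enrichment(
    target_genes: Sequence[str],
    genesets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    drop_top_k: Union[int, Sequence[int]] = 0,
) -> pd.DataFrame:
    """One-sided hypergeometric gene-set enrichment with top-k removal.

    ``target_genes`` must be ranked by insertion count (most-hit first);
    for each k in ``drop_top_k`` the k most-hit genes are removed before
    testing, producing the robustness profile of enrichment that survives
    deletion of the strongest targets.  Sets with no gene in the universe
    are skipped with a warning.
    """
    import warnings

    ks = [drop_top_k] if isinstance(drop_top_k, int) else list(drop_top_k)
    uni = set(universe)
    missing = set(target_genes) - uni
    if missing:
        raise ValidationError(f"target genes outside the universe: {sorted(missing)[:5]}...")
    rows = []
    for k in ks:
        targets = [g for g in target_genes[k:]]
        tset = set(targets)
        for name, genes in genesets.items():
            in_uni = [g for g in dict.fromkeys(genes) if g in uni]
            if not in_uni:
                warnings.warn(f"gene set {name!r} has no members in the universe; skipped")
                continue
            overlap = len(tset & set(in_uni))
            M, K, n = len(uni), len(in_uni), len(tset)
            p = float(stats.hypergeom.sf(overlap - 1, M, K, n)) if n else 1.0
            rows.append((k, name, len(in_uni), n, overlap, p))
    return pd.DataFrame(
        rows, columns=["drop_top_k", "geneset", "set_size", "n_targets", "overlap", "p"]
    )
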