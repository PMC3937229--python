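"""Common-insertion-site detection by multi-scale Gaussian kernel convolution.

Unique insertion positions are smoothed with an unnormalised Gaussian
kernel, f(x) = sum_i exp(-(x - x_i)^2 / (2 sigma^2)), at a ladder of
kernel widths.  Per scale, a genome-wide significance threshold on the
peak height is calibrated by Monte Carlo: cohorts of the same size are
placed uniformly over the genome and the (1 - alpha) quantile of their
genome-wide maximum height becomes the calling threshold (a max-statistic
family-wise control, so a uniformly integrating cohort yields a CIS in
only ~alpha of runs per scale).  Contiguous above-threshold stretches
become candidate CISs; candidates overlapping across scales are
consolidated, reporting each cluster at its matched (best
height-to-threshold) scale.

Also provides the fixed-window cluster rule (>= 3 sites within a 12,587 nt
span) used for near-baseline vector integration datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CIS, GenomeModel, ValidationError

DEFAULT_SCALES = (
    2_000.0,
    5_000.0,
    10_000.0,
    15_000.0,
    30_000.0,
    60_000.0,
    120_000.0,
    250_000.0,
    500_000.0,
)

# kernel support cutoff and candidate-window margin, in units of sigma
_CUTOFF = 6.0
_WINDOW = 4.0
_MAX_PAIR_CHUNK = 4_000_000


@dataclass
class GkcConfig:
    """Configuration of the multi-scale GKC caller.

    scales : kernel widths sigma in bp, ascending.  The default ladder
        spans tight intragenic clusters (2 kb) up to long-range
        enhancer-mode targets (500 kb) and includes the 15 kb and 30 kb
        anchor scales.
    alpha : genome-wide significance level per scale (max-statistic).
    n_null : Monte-Carlo draws for threshold calibration (>= 100).
    grid_step : density evaluation step as a fraction of sigma.
    seed : seed for the null draws.
    min_insertions : minimum members per CIS.
    min_samples : minimum distinct samples per CIS (1 = within-tumour
        recurrence counts too).
    read_weighted : weight each insertion by its read count instead of 1.
    """

    scales: tuple[float, ...] = DEFAULT_SCALES
    alpha: float = 0.05
    n_null: int = 100
    grid_step: float = 0.25
    seed: Optional[int] = None
    min_insertions: int = 2
    min_samples: int = 1
    read_weighted: bool = False

    def __post_init__(self) -> None:
        self.scales = tuple(float(s) for s in self.scales)
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValidationError("scales must be positive")
        if list(self.scales) != sorted(self.scales):
            raise ValidationError("scales must be sorted ascending")
        if not (0 < self.alpha <= 1):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.n_null < 100:
            raise ValidationError(f"n_null must be >= 100, got {self.n_null}")
        if self.grid_step <= 0:
            raise ValidationError("grid_step must be positive")


def gaussian_sum(
    sites: np.ndarray,
    xs: np.ndarray,
    sigma: float,
    weights: Optional[np.ndarray] = None,
    cutoff: float = _CUTOFF,
) -> np.ndarray:
    """Exact f(x) = sum_i w_i exp(-(x - x_i)^2 / (2 sigma^2)) at each x.

    ``sites`` must be sorted; only sites within ``cutoff`` sigma of each x
    contribute (exp(-18) ~ 1.5e-8 at the default cutoff).
    """
    sites = np.asarray(sites, dtype=np.float64)
    xs = np.asarray(xs, dtype=np.float64)
    out = np.zeros(len(xs), dtype=np.float64)
    if not len(sites) or not len(xs):
        return out
    half = cutoff * sigma
    lo = np.searchsorted(sites, xs - half, side="left")
    hi = np.searchsorted(sites, xs + half, side="right")
    counts = hi - lo
    # chunk over xs so the flattened pair arrays stay bounded
    csum = np.cumsum(counts)
    start = 0
    while start < len(xs):
        base = csum[start - 1] if start else 0
        end = int(np.searchsorted(csum, base + _MAX_PAIR_CHUNK, side="left")) + 1
        end = min(max(end, start + 1), len(xs))
        c = counts[start:end]
        total = int(c.sum())
        if total:
            offsets = np.cumsum(c) - c
            within = np.arange(total, dtype=np.int64) - np.repeat(offsets, c)
            idx = np.repeat(lo[start:end], c) + within
            d = (np.repeat(xs[start:end], c) - sites[idx]) / sigma
            contrib = np.exp(-0.5 * d * d)
            if weights is not None:
                contrib *= weights[idx]
            seg = np.repeat(np.arange(end - start, dtype=np.int64), c)
            out[start:end] = np.bincount(seg, weights=contrib, minlength=end - start)
        start = end
    return out


def _eval_points(
    positions: np.ndarray, sigma: float, grid_step: float, chrom_length: Optional[int] = None
) -> np.ndarray:
    """Grid over merged +/- _WINDOW*sigma site neighbourhoods, plus the sites.

    The density is below any useful threshold farther than ~4 sigma from
    every site, so evaluation is restricted to these windows; site
    positions themselves are always included exactly.
    """
    if not len(positions):
        return np.empty(0, dtype=np.float64)
    step = max(1.0, grid_step * sigma)
    half = _WINDOW * sigma
    lo = positions - half
    hi = positions + half
    if chrom_length is not None:
        lo = np.clip(lo, 1, chrom_length)
        hi = np.clip(hi, 1, chrom_length)
    # merge overlapping windows (positions sorted)
    brk = np.flatnonzero(lo[1:] > hi[:-1]) + 1
    seg_lo = lo[np.concatenate([[0], brk])]
    seg_hi = hi[np.concatenate([brk - 1, [len(hi) - 1]])]
    grids = [np.arange(a, b + step, step) for a, b in zip(seg_lo, seg_hi)]
    xs = np.unique(np.concatenate(grids + [positions.astype(np.float64)]))
    return xs


def kde_profile(
    positions: Sequence[float],
    scale: float,
    grid_step: float = 0.25,
    weights: Optional[np.ndarray] = None,
    chrom_length: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian kernel density of one chromosome's insertion positions.

    Returns (xs, f(xs)) where xs is a grid of step ``grid_step * scale``
    over the site neighbourhoods, with the exact site positions included
    as evaluation points.  Each unique RIS contributes weight 1 unless
    ``weights`` is given.  Empty input yields an empty (zero) profile.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    positions = np.sort(np.asarray(positions, dtype=np.float64))
    xs = _eval_points(positions, scale, grid_step, chrom_length)
    return xs, gaussian_sum(positions, xs, scale, weights=weights)


def _positions_by_chrom(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(grp["pos"].to_numpy(np.float64))
        for chrom, grp in cohort.groupby("chrom", sort=True)
    }


def _null_max_heights(
    n_sites: int,
    genome: GenomeModel,
    scales: Sequence[float],
    n_null: int,
    seed: Optional[int],
    grid_step: float,
) -> np.ndarray:
    """(n_null, n_scales) genome-wide maximum heights of uniform cohorts."""
    rng = np.random.default_rng(seed)
    maxima = np.zeros((n_null, len(scales)))
    for d in range(n_null):
        draw = genome.uniform_positions(n_sites, rng)
        for chrom, grp in draw.groupby("chrom", sort=False):
            pos = np.sort(grp["pos"].to_numpy(np.float64))
            L = genome.chrom_lengths[chrom]
            for j, sigma in enumerate(scales):
                xs = _eval_points(pos, sigma, grid_step, L)
                f = gaussian_sum(pos, xs, sigma)
                if len(f):
                    m = f.max()
                    if m > maxima[d, j]:
                        maxima[d, j] = m
    return maxima


def null_thresholds(
    n_sites: int,
    genome: GenomeModel,
    config: GkcConfig,
) -> dict[float, float]:
    """Per-scale calling thresholds from the uniform-integration null.

    For each of ``config.n_null`` draws, ``n_sites`` positions are placed
    uniformly over the genome (per-chromosome probability proportional to
    length) and the genome-wide maximum kernel height is recorded per
    scale; the threshold is the (1 - alpha) empirical quantile of those
    maxima.
    """
    if n_sites < 2:
        raise ValidationError("null calibration needs n_sites >= 2")
    maxima = _null_max_heights(
        n_sites, genome, config.scales, config.n_null, config.seed, config.grid_step
    )
    q = np.quantile(maxima, 1.0 - config.alpha, axis=0)
    return {s: float(t) for s, t in zip(config.scales, q)}


def null_threshold(
    n_sites: int,
    genome: GenomeModel,
    scale: float,
    alpha: float,
    n_null: int,
    seed: Optional[int] = None,
    grid_step: float = 0.25,
) -> float:
    """Single-scale convenience wrapper around :func:`null_thresholds`."""
    cfg = GkcConfig(scales=(scale,), alpha=alpha, n_null=n_null, seed=seed, grid_step=grid_step)
    return null_thresholds(n_sites, genome, cfg)[scale]


@dataclass
class _Candidate:
    chrom: str
    scale: float
    start: int  # member-extent, 1-based inclusive
    end: int
    peak_pos: int
    peak_height: float
    member_rows: np.ndarray


def _candidates_one_scale(
    chrom: str,
    pos: np.ndarray,
    rows: np.ndarray,
    sigma: float,
    threshold: float,
    config: GkcConfig,
    chrom_length: int,
    weights: Optional[np.ndarray],
) -> list[_Candidate]:
    xs = _eval_points(pos, sigma, config.grid_step, chrom_length)
    f = gaussian_sum(pos, xs, sigma, weights=weights)
    above = f > threshold
    if not above.any():
        return []
    step = max(1.0, config.grid_step * sigma)
    out: list[_Candidate] = []
    i = 0
    n = len(xs)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and (xs[j + 1] - xs[j]) <= 1.5 * step:
            j += 1
        lo_x, hi_x = xs[i], xs[j]
        m = (pos >= lo_x) & (pos <= hi_x)
        if m.sum() >= config.min_insertions:
            mpos = pos[m]
            start, end = int(mpos.min()), int(mpos.max())
            seg = slice(i, j + 1)
            k = int(np.argmax(f[seg])) + i
            peak = int(round(xs[k]))
            peak = min(max(peak, start), end)  # argmax ties/margins clamp into extent
            out.append(
                _Candidate(chrom, sigma, start, end, peak, float(f[seg].max()), rows[m])
            )
        i = j + 1
    return out


def _consolidate(
    cands: list[_Candidate],
    cohort: pd.DataFrame,
    config: GkcConfig,
    thresholds: dict[float, float],
) -> list[CIS]:
    """Merge candidates overlapping by >= 1 nt across scales.

    Within each connected overlap component the cluster is reported at
    its matched scale: the scale whose candidate maximises peak height
    relative to that scale's null threshold (the matched-filter scale,
    at which the kernel width best fits the cluster).  Every candidate
    at that scale in the component becomes a CIS, so distinct tight
    clusters bridged only by a coarse-scale candidate stay separate.
    The component's full extent, its set of significant scales and the
    union of members over all scales are recorded on each CIS
    (``envelope``, ``supporting_scales``, ``all_member_index``); the
    reported extent spans the reported members' min/max coordinates,
    keeping CIS widths at the resolution that detected them.
    """
    out: list[CIS] = []
    by_chrom: dict[str, list[_Candidate]] = {}
    for c in cands:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        comp_end = -1
        comp: list[_Candidate] = []
        groups: list[list[_Candidate]] = []
        for c in items:
            if comp and c.start > comp_end:
                groups.append(comp)
                comp = []
                comp_end = -1
            comp.append(c)
            comp_end = max(comp_end, c.end)
        if comp:
            groups.append(comp)
        for grp in groups:
            best = max(grp, key=lambda c: c.peak_height / thresholds[c.scale])
            s_rep = best.scale
            union = np.unique(np.concatenate([c.member_rows for c in grp]))
            envelope = (min(c.start for c in grp), max(c.end for c in grp))
            scales = tuple(sorted({c.scale for c in grp}))
            for rep in sorted(
                (c for c in grp if c.scale == s_rep), key=lambda c: (c.start, c.end)
            ):
                members = rep.member_rows
                n_samples = int(cohort.iloc[members]["sample_id"].nunique())
                if len(members) < config.min_insertions or n_samples < config.min_samples:
                    continue
                out.append(
                    CIS(
                        chrom=chrom,
                        start=rep.start,
                        end=rep.end,
                        peak_pos=rep.peak_pos,
                        peak_height=rep.peak_height,
                        scale=rep.scale,
                        member_index=members,
                        n_samples=n_samples,
                        supporting_scales=scales,
                        envelope=envelope,
                        all_member_index=union,
                    )
                )
    return out


def call_cis(
    cohort: pd.DataFrame,
    genome: GenomeModel,
    config: Optional[GkcConfig] = None,
    thresholds: Optional[dict[float, float]] = None,
) -> list[CIS]:
    """Call CISs on a merged-RIS cohort by multi-scale GKC.

    ``thresholds`` (scale -> height) may be supplied to reuse a null
    calibration computed at the same cohort size; otherwise the null is
    simulated here via :func:`null_thresholds`.
    """
    config = config or GkcConfig()
    if len(cohort) < max(2, config.min_insertions):
        return []
    if thresholds is None:
        thresholds = null_thresholds(len(cohort), genome, config)
    missing = [s for s in config.scales if s not in thresholds]
    if missing:
        raise ValidationError(f"thresholds missing scales {missing}")
    cohort = cohort.reset_index(drop=True)
    weights_all = cohort["reads"].to_numpy(np.float64) if config.read_weighted else None
    cands: list[_Candidate] = []
    chrom_col = cohort["chrom"].to_numpy()
    for chrom, grp in cohort.groupby("chrom", sort=True):
        order = np.argsort(grp["pos"].to_numpy(), kind="mergesort")
        rows = np.flatnonzero(chrom_col == chrom)[order]
        pos = grp["pos"].to_numpy(np.float64)[order]
        w = weights_all[rows] if weights_all is not None else None
        L = genome.chrom_lengths.get(chrom)
        if L is None:
            raise ValidationError(f"cohort chromosome {chrom!r} not in genome")
        for sigma in config.scales:
            cands.extend(
                _candidates_one_scale(chrom, pos, rows, sigma, thresholds[sigma], config, L, w)
            )
    return _consolidate(cands, cohort, config, thresholds)


@dataclass
class WindowCluster:
    """A fixed-window integration cluster (no kernel statistics)."""

    chrom: str
    start: int
    end: int
    n_sites: int
    member_index: np.ndarray

    def members(self, cohort: pd.DataFrame) -> pd.DataFrame:
        return cohort.iloc[self.member_index]


def cluster_window(
    sites: pd.DataFrame,
    window: int = 12_587,
    min_sites: int = 3,
) -> list[WindowCluster]:
    """Greedy fixed-window clustering of integration sites.

    Per chromosome, scanning left to right from each unassigned leftmost
    site, a region grows while its spanned width (max - min + 1 nt) stays
    <= ``window``; it is emitted when it holds >= ``min_sites`` sites.
    Clusters are disjoint.  This is the rule used for near-baseline vector
    datasets (>= 3 sites within 12,587 nt).
    """
    out: list[WindowCluster] = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        order = np.argsort(grp["pos"].to_numpy(), kind="mergesort")
        pos = grp["pos"].to_numpy(np.int64)[order]
        rows = np.flatnonzero((sites["chrom"] == chrom).to_numpy())[order]
        i = 0
        n = len(pos)
        while i < n:
            j = int(np.searchsorted(pos, pos[i] + window - 1, side="right")) - 1
            if j - i + 1 >= min_sites:
                out.append(
                    WindowCluster(chrom, int(pos[i]), int(pos[j]), j - i + 1, rows[i : j + 1])
                )
                i = j + 1
            else:
                i += 1
    return out
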