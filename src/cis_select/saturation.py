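"""Saturation analysis: pseudo-kernel coverage as a function of cohort size.

Each sample's insertion sites are expanded into +/- 7.5 kb pseudo-kernels
(mimicking 15 kb GKC kernels) and merged within the sample.  For every
subset size n, the union base-pair coverage over random (or exhaustive,
when feasible) n-sample combinations is summarised by its median and
quartiles.  A screen that has found most selectable targets shows the
real curve bending toward a plateau while a random-placement control
stays linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomeModel, ValidationError


@dataclass
class SaturationCurve:
    """Coverage quartiles per subset size for one condition."""

    table: pd.DataFrame  # columns: n, q25, median, q75, n_combinations
    label: str  # 'real' or 'random_control'
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and not ((t["q25"] <= t["median"]) & (t["median"] <= t["q75"])).all():
            raise ValidationError("quartiles out of order")


def pseudo_kernel_regions(
    sites: pd.DataFrame,
    genome: GenomeModel,
    half_width: int = 7_500,
) -> dict[str, np.ndarray]:
    """Merged +/- half_width pseudo-kernel intervals of one sample's sites.

    Each site becomes the half-open interval [pos - half_width,
    pos + half_width) clipped to the chromosome, so an interior site
    covers exactly 2 * half_width = 15,000 bp; overlapping or adjacent
    intervals within the sample are merged.  Returns per-chromosome
    (n, 2) interval arrays.
    """
    if half_width <= 0:
        raise ValidationError("half_width must be positive")
    out: dict[str, np.ndarray] = {}
    for chrom, grp in sites.groupby("chrom", sort=True):
        L = genome.chrom_lengths.get(chrom)
        if L is None:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        pos = np.sort(grp["pos"].to_numpy(np.int64))
        lo = np.clip(pos - half_width, 0, L)
        hi = np.clip(pos + half_width, 0, L)
        merged = []
        cur_lo, cur_hi = int(lo[0]), int(hi[0])
        for a, b in zip(lo[1:], hi[1:]):
            if a <= cur_hi:  # overlapping or adjacent
                cur_hi = max(cur_hi, int(b))
            else:
                merged.append((cur_lo, cur_hi))
                cur_lo, cur_hi = int(a), int(b)
        merged.append((cur_lo, cur_hi))
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def _union_coverage(per_sample: Sequence[Mapping[str, np.ndarray]]) -> int:
    """Total bp covered by the union of several samples' interval maps."""
    chroms: set[str] = set()
    for m in per_sample:
        chroms.update(m)
    total = 0
    for chrom in chroms:
        ivs = [m[chrom] for m in per_sample if chrom in m]
        iv = np.concatenate(ivs)
        iv = iv[np.argsort(iv[:, 0], kind="mergesort")]
        starts, ends = iv[:, 0], iv[:, 1]
        # sweep: a new covered block starts where start > running max end
        run_max = np.maximum.accumulate(ends)
        new_block = np.concatenate([[True], starts[1:] > run_max[:-1]])
        block_id = np.cumsum(new_block) - 1
        block_end = np.zeros(block_id[-1] + 1, dtype=np.int64)
        np.maximum.at(block_end, block_id, ends)
        block_start = starts[new_block]
        total += int((block_end - block_start).sum())
    return total


def coverage_curve(
    samples: Mapping[str, pd.DataFrame],
    genome: GenomeModel,
    half_width: int = 7_500,
    max_combos: int = 1_000,
    seed: Optional[int] = None,
    label: str = "real",
) -> SaturationCurve:
    """Pseudo-kernel coverage quartiles over sample combinations.

    For each subset size n in 1..N, coverage is evaluated for every
    n-combination when C(N, n) <= ``max_combos``, otherwise for
    ``max_combos`` distinct combinations sampled without replacement
    (seeded).  Medians are non-decreasing in n in expectation; exhaustive
    evaluation is exact for small N.
    """
    names = sorted(samples)
    N = len(names)
    if N < 2:
        raise ValidationError("saturation needs >= 2 samples")
    kernels = {name: pseudo_kernel_regions(samples[name], genome, half_width) for name in names}
    rng = np.random.default_rng(seed)
    rows = []
    for n in range(1, N + 1):
        n_comb = math.comb(N, n)
        if n_comb <= max_combos:
            subsets = list(combinations(range(N), n))
        else:
            chosen: set[tuple[int, ...]] = set()
            while len(chosen) < max_combos:
                chosen.add(tuple(sorted(rng.choice(N, size=n, replace=False))))
            subsets = sorted(chosen)
        cov = np.array(
            [_union_coverage([kernels[names[i]] for i in sub]) for sub in subsets], dtype=float
        )
        q25, med, q75 = np.percentile(cov, [25, 50, 75])
        rows.append((n, q25, med, q75, len(subsets)))
    table = pd.DataFrame(rows, columns=["n", "q25", "median", "q75", "n_combinations"])
    return SaturationCurve(table, label=label, seed=seed)


def random_control(
    samples: Mapping[str, pd.DataFrame],
    genome: GenomeModel,
    half_width: int = 7_500,
    max_combos: int = 1_000,
    seed: Optional[int] = None,
) -> SaturationCurve:
    """Coverage curve after replacing each sample's sites with the same
    number of uniform random genomic positions (seeded)."""
    rng = np.random.default_rng(seed)
    randomised = {}
    for name in sorted(samples):
        n = len(samples[name])
        draw = genome.uniform_positions(n, rng)
        randomised[name] = pd.DataFrame({"chrom": draw["chrom"], "pos": draw["pos"]})
    curve = coverage_curve(
        randomised, genome, half_width=half_width, max_combos=max_combos, seed=seed,
        label="random_control",
    )
    return curve


def split_by_sample(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cohort frame -> per-sample frames keyed by sample_id."""
    return {name: grp.reset_index(drop=True) for name, grp in cohort.groupby("sample_id")}


def marginal_gain(curve: SaturationCurve, n: int) -> float:
    """Median coverage gained by adding the n-th sample (median(n) - median(n-1))."""
    t = curve.table.set_index("n")["median"]
    if n < 2 or n not in t.index or (n - 1) not in t.index:
        raise ValidationError(f"marginal gain undefined at n={n}")
    return float(t.loc[n] - t.loc[n - 1])
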