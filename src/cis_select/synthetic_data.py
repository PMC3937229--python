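"""Synthetic integration cohorts with known ground truth.

The generator emulates the statistical structure a gamma-retroviral
screen's analysis assumes, as a two-stage process: (1) integration
preference — background insertions fall near transcription start sites
with probability ``tss_weight`` (signed Laplace offset of scale
``tss_decay``) and uniformly otherwise; (2) oncogenic selection — each
driver locus is carried by a sample with probability ``selection_prob``,
its insertion lands within ``window`` bp of the locus with a preferred
orientation (probability ``orientation_prob``), and the resulting
expanded clone receives >= 100 reads (shifted log-normal) plus passenger
insertions at uniform positions that share the clone's read count
exactly (co-amplification).  Background reads stay in 1..99, so the
100-read expansion threshold separates planted clones exactly.

Every cohort is deterministic for a fixed config seed and is accompanied
by a truth table for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    COHORT_COLUMNS,
    FORWARD,
    GenomeModel,
    MM9_CHROM_LENGTHS,
    REVERSE,
    ValidationError,
    coerce_cohort,
    mm9_like_genome,
)


@dataclass(frozen=True)
class DriverSpec:
    """One selected locus: where insertions land and how they behave."""

    driver_id: str
    chrom: str
    locus: int  # 1-based
    window: int  # insertions uniform in [locus - window, locus + window]
    orientation_prob: float  # P(forward strand), in [0.5, 1]
    selection_prob: float  # per-sample probability of carrying the driver
    genotypes: Optional[tuple[str, ...]] = None  # restriction; None = any

    def __post_init__(self) -> None:
        if not (0.5 <= self.orientation_prob <= 1.0):
            raise ValidationError("orientation_prob must be in [0.5, 1]")
        if not (0.0 <= self.selection_prob <= 1.0):
            raise ValidationError("selection_prob must be in [0, 1]")
        if self.window < 0 or self.locus < 1:
            raise ValidationError("driver locus/window invalid")


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic cohort.  ``seed`` is mandatory."""

    seed: int
    n_samples: int = 28
    genotypes: Optional[tuple[str, ...]] = None  # one label per sample
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(MM9_CHROM_LENGTHS))
    n_genes: int = 20_000
    background_sites_per_sample: int = 366
    tss_weight: float = 0.2  # w: fraction of background integrating near a TSS
    tss_decay: float = 5_000.0  # tau: Laplace scale of the TSS offset, bp
    drivers: tuple[DriverSpec, ...] = ()
    passenger_mean: float = 1.0  # Poisson mean passengers per expanded clone
    expansion_mu: float = 5.5  # log-scale of the shifted log-normal clone reads
    expansion_sigma: float = 1.2
    expansion_floor: int = 100
    background_read_p: float = 0.35  # geometric; capped at expansion_floor - 1

    def __post_init__(self) -> None:
        if self.genotypes is None:
            self.genotypes = ("wt",) * self.n_samples
        if len(self.genotypes) != self.n_samples:
            raise ValidationError("genotypes must have one label per sample")
        if not (0.0 <= self.tss_weight <= 1.0):
            raise ValidationError("tss_weight must be in [0, 1]")
        if self.tss_decay <= 0 or self.background_sites_per_sample < 0:
            raise ValidationError("invalid background parameters")
        for d in self.drivers:
            L = self.chrom_lengths.get(d.chrom)
            if L is None or not (1 <= d.locus <= L):
                raise ValidationError(f"driver {d.driver_id} locus outside genome")

    @property
    def sample_ids(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``table`` is row-aligned with the cohort frame: role is one of
    driver / passenger / background, with driver_id and clone_id set for
    planted-clone insertions.  ``carriers`` maps driver_id to the samples
    that carry it; ``drivers`` echoes the planted specs.
    """

    table: pd.DataFrame  # columns: role, driver_id, clone_id
    carriers: dict[str, list[str]]
    drivers: tuple[DriverSpec, ...]


def build_genome(config: SimConfig) -> GenomeModel:
    """The deterministic genome (chromosomes + synthetic genes) of a config."""
    gseed = np.random.SeedSequence([int(config.seed), 0])
    return mm9_like_genome(
        n_genes=config.n_genes,
        seed=gseed,
        chrom_lengths=config.chrom_lengths,
    )


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a cohort of insertion sites plus its truth table."""
    genome = build_genome(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    cap = config.expansion_floor - 1
    tss = genome.tss_table
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    carriers: dict[str, list[str]] = {d.driver_id: [] for d in config.drivers}

    for sample, genotype in zip(config.sample_ids, config.genotypes):
        # background integration: TSS-preferential mixture
        n_b = config.background_sites_per_sample
        near = rng.random(n_b) < config.tss_weight
        uni = genome.uniform_positions(n_b, rng)
        chroms = uni["chrom"].to_numpy(object)
        pos = uni["pos"].to_numpy(np.int64)
        n_near = int(near.sum())
        if n_near and tss is not None and len(tss):
            pick = rng.integers(0, len(tss), size=n_near)
            offs = np.rint(rng.laplace(0.0, config.tss_decay, size=n_near)).astype(np.int64)
            tpos = tss["tss_pos"].to_numpy(np.int64)[pick] + offs
            tchrom = tss["chrom"].to_numpy(object)[pick]
            lens = np.array([config.chrom_lengths[c] for c in tchrom], dtype=np.int64)
            chroms[near] = tchrom
            pos[near] = np.clip(tpos, 1, lens)
        strands = np.where(rng.random(n_b) < 0.5, FORWARD, REVERSE)
        reads = np.minimum(rng.geometric(config.background_read_p, size=n_b), cap)
        for c, p, s, r in zip(chroms, pos, strands, reads):
            rows.append((c, int(p), s, sample, genotype, int(r)))
            truth_rows.append(("background", "", ""))

        # selected drivers and their expanded clones
        for d in config.drivers:
            if d.genotypes is not None and genotype not in d.genotypes:
                continue
            if rng.random() >= d.selection_prob:
                continue
            carriers[d.driver_id].append(sample)
            L = config.chrom_lengths[d.chrom]
            lo = max(1, d.locus - d.window)
            hi = min(L, d.locus + d.window)
            p = int(rng.integers(lo, hi + 1))
            strand = FORWARD if rng.random() < d.orientation_prob else REVERSE
            clone_reads = config.expansion_floor + int(
                np.rint(rng.lognormal(config.expansion_mu, config.expansion_sigma))
            )
            clone_id = f"{sample}:{d.driver_id}"
            rows.append((d.chrom, p, strand, sample, genotype, clone_reads))
            truth_rows.append(("driver", d.driver_id, clone_id))
            # passenger co-amplification: same clone, same read count
            for _ in range(int(rng.poisson(config.passenger_mean))):
                u = genome.uniform_positions(1, rng)
                s = FORWARD if rng.random() < 0.5 else REVERSE
                rows.append(
                    (u["chrom"].iloc[0], int(u["pos"].iloc[0]), s, sample, genotype, clone_reads)
                )
                truth_rows.append(("passenger", d.driver_id, clone_id))

    cohort = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    truth = pd.DataFrame(truth_rows, columns=["role", "driver_id", "clone_id"])
    # reproducible joint ordering, keeping cohort and truth row-aligned
    order = cohort.sort_values(
        ["chrom", "pos", "strand", "sample_id"], kind="mergesort"
    ).index.to_numpy()
    cohort = coerce_cohort(cohort.iloc[order].reset_index(drop=True))
    truth = truth.iloc[order].reset_index(drop=True)
    return cohort, SimTruth(truth, carriers, tuple(config.drivers))


def default_screen_config(seed: int = 1) -> SimConfig:
    """The default study design: 28 tumours, ~12,485 sites, 50 drivers.

    Thirty drivers are enhancer-mode (orientation_prob 0.9) and twenty are
    orientation-neutral intragenic-style (0.5), a 60/40 mix; all have
    per-sample selection probability 0.8.  Driver loci are placed >= 5 Mb
    apart so called clusters stay distinct.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    lengths = dict(MM9_CHROM_LENGTHS)
    genome = GenomeModel(lengths)
    margin = 1_000_000
    min_sep = 5_000_000
    loci: list[tuple[str, int]] = []
    while len(loci) < 50:
        draw = genome.uniform_positions(1, rng)
        chrom, pos = draw["chrom"].iloc[0], int(draw["pos"].iloc[0])
        if pos < margin or pos > lengths[chrom] - margin:
            continue
        if any(c == chrom and abs(p - pos) < min_sep for c, p in loci):
            continue
        loci.append((chrom, pos))
    enhancer_windows = np.array([5_000, 10_000, 20_000])
    intragenic_windows = np.array([2_000, 5_000, 10_000])
    drivers = []
    for i, (chrom, pos) in enumerate(loci):
        enhancer = i < 30
        drivers.append(
            DriverSpec(
                driver_id=f"drv{i:02d}",
                chrom=chrom,
                locus=pos,
                window=int(rng.choice(enhancer_windows if enhancer else intragenic_windows)),
                orientation_prob=0.9 if enhancer else 0.5,
                selection_prob=0.8,
            )
        )
    return SimConfig(seed=int(seed), drivers=tuple(drivers))


@dataclass
class RecoveryScore:
    """Driver-recovery metrics of a CIS call set against simulation truth."""

    sensitivity: float
    false_cis_rate: float
    biased_recall: float
    biased_false_flag: float
    n_eligible_drivers: int
    n_called: int


def score_recovery(
    called_cis: Sequence,
    truth: SimTruth,
    biased_indices: Optional[Sequence[int]] = None,
) -> RecoveryScore:
    """Score a CIS call set against the planted truth.

    sensitivity: fraction of drivers with >= 2 planted insertions whose
    locus lies inside a called CIS extent.  false_cis_rate: fraction of
    called CISs containing no driver-role insertion.  Biased-set metrics
    (versus ``biased_indices`` into ``called_cis``): recall over eligible
    drivers with orientation_prob > 0.5, false-flag rate over eligible
    orientation-neutral drivers.
    """
    per_driver_n = truth.table[truth.table["role"] == "driver"]["driver_id"].value_counts()
    eligible = [d for d in truth.drivers if per_driver_n.get(d.driver_id, 0) >= 2]

    def contains(cis, d: DriverSpec) -> bool:
        return cis.chrom == d.chrom and cis.start <= d.locus <= cis.end

    hit = {d.driver_id: any(contains(c, d) for c in called_cis) for d in eligible}
    sensitivity = (sum(hit.values()) / len(eligible)) if eligible else float("nan")

    roles = truth.table["role"].to_numpy()
    n_false = sum(1 for c in called_cis if not (roles[c.member_index] == "driver").any())
    false_rate = (n_false / len(called_cis)) if called_cis else 0.0

    biased_recall = float("nan")
    biased_false = float("nan")
    if biased_indices is not None:
        biased = [called_cis[i] for i in biased_indices]
        flagged = {d.driver_id: any(contains(c, d) for c in biased) for d in eligible}
        enh = [d for d in eligible if d.orientation_prob > 0.5]
        neu = [d for d in eligible if d.orientation_prob == 0.5]
        if enh:
            biased_recall = sum(flagged[d.driver_id] for d in enh) / len(enh)
        if neu:
            biased_false = sum(flagged[d.driver_id] for d in neu) / len(neu)
    return RecoveryScore(
        sensitivity=float(sensitivity),
        false_cis_rate=float(false_rate),
        biased_recall=float(biased_recall),
        biased_false_flag=float(biased_false),
        n_eligible_drivers=len(eligible),
        n_called=len(called_cis),
    )


def tss_covered_fraction(genome: GenomeModel, half_width: float) -> float:
    """Fraction of the genome within ``half_width`` bp of any TSS."""
    if genome.tss_table is None or not len(genome.tss_table):
        return 0.0
    covered = 0
    for chrom, grp in genome.tss_table.groupby("chrom"):
        L = genome.chrom_lengths[chrom]
        pos = np.sort(grp["tss_pos"].to_numpy(np.int64))
        lo = np.clip(pos - half_width, 0, L)
        hi = np.clip(pos + half_width, 0, L)
        cur_lo, cur_hi = lo[0], hi[0]
        for a, b in zip(lo[1:], hi[1:]):
            if a <= cur_hi:
                cur_hi = max(cur_hi, b)
            else:
                covered += cur_hi - cur_lo
                cur_lo, cur_hi = a, b
        covered += cur_hi - cur_lo
    return float(covered) / genome.total_length


def estimate_tss_weight(
    signed_distances: np.ndarray,
    genome: GenomeModel,
    tau: float,
    cutoff_mult: float = 5.0,
) -> float:
    """Recover the TSS-preference weight w from nearest-TSS distances.

    Method of moments on the near-TSS fraction: within c = cutoff_mult *
    tau of a TSS, a Laplace-displaced site lands with probability
    1 - exp(-c / tau) while a uniform site lands with the genome's
    TSS-neighbourhood fraction; solving the two-component mixture for w.
    """
    d = np.asarray(signed_distances, dtype=float)
    d = d[~np.isnan(d)]
    c = cutoff_mult * tau
    near_frac = float((np.abs(d) <= c).mean())
    p_unif = tss_covered_fraction(genome, c)
    p_lap = 1.0 - np.exp(-c / tau)
    if p_lap <= p_unif:
        raise ValidationError("degenerate mixture: Laplace cutoff no tighter than uniform")
    w = (near_frac - p_unif) / (p_lap - p_unif)
    return float(np.clip(w, 0.0, 1.0))
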