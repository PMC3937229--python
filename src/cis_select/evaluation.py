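"""Study-scale reference evaluations on synthetic cohorts.

These functions reproduce the screen-scale behaviour of the pipeline
under controlled conditions: uniform-integration nulls at the full
cohort size, driver recovery on the default study design, orientation
tests under strand randomisation, and the saturation signature of a
driver-saturated cohort.  They are used by the analysis scripts, the
acceptance checks and anyone wanting a calibrated end-to-end run.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cis_detection import GkcConfig, call_cis, null_thresholds
from .core import GenomeModel, coerce_cohort, mm9_like_genome
from .ris_processing import merge_sites
from .saturation import coverage_curve, marginal_gain, random_control
from .selection_stats import (
    bh_adjust,
    biased_cis_set,
    orientation_pvalues_vectorised,
    orientation_test_all,
)
from .synthetic_data import default_screen_config, score_recovery, simulate_cohort

#: nominal cohort size of the reference screen (28 tumours)
NOMINAL_COHORT_SIZE = 12_485
NOMINAL_N_SAMPLES = 28


def uniform_pseudo_cohort(
    genome: GenomeModel,
    n_sites: int,
    n_samples: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """A cohort of uniformly integrated sites split over pseudo-samples."""
    draw = genome.uniform_positions(n_sites, rng)
    return coerce_cohort(
        pd.DataFrame(
            {
                "chrom": draw["chrom"],
                "pos": draw["pos"],
                "strand": np.where(rng.random(n_sites) < 0.5, "+", "-"),
                "sample_id": [f"S{i % n_samples:02d}" for i in range(n_sites)],
                "genotype": "",
                "reads": 1,
            }
        )
    )


def uniform_null_cis_counts(
    genome: GenomeModel,
    config: GkcConfig,
    thresholds: dict[float, float],
    n_cohorts: int = 10,
    n_sites: int = NOMINAL_COHORT_SIZE,
    n_samples: int = NOMINAL_N_SAMPLES,
    seed: int = 0,
) -> list[int]:
    """CIS counts called on fresh uniform cohorts (the random-integration null).

    Each cohort is merged (3-nt rule) before calling, mirroring the real
    processing chain.
    """
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_cohorts):
        cohort = uniform_pseudo_cohort(genome, n_sites, n_samples, rng)
        cohort = merge_sites(cohort)
        counts.append(len(call_cis(cohort, genome, config, thresholds=thresholds)))
    return counts


def recovery_over_seeds(
    genome: GenomeModel,
    config: GkcConfig,
    thresholds: dict[float, float],
    seeds: Sequence[int] = tuple(range(1, 11)),
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Driver-recovery metrics of the default study design, one row per seed."""
    rows = []
    for seed in seeds:
        cohort, truth = simulate_cohort(default_screen_config(seed=seed))
        cohort = merge_sites(cohort)
        cis = call_cis(cohort, genome, config, thresholds=thresholds)
        results = orientation_test_all(cis, cohort)
        biased_idx = [i for i, r in enumerate(results) if r.q < q_cut]
        s = score_recovery(cis, truth, biased_indices=biased_idx)
        rows.append(
            (seed, len(cohort), s.n_called, s.sensitivity, s.false_cis_rate,
             s.biased_recall, s.biased_false_flag)
        )
    return pd.DataFrame(
        rows,
        columns=["seed", "n_sites", "n_cis", "sensitivity", "false_cis_rate",
                 "biased_recall", "biased_false_flag"],
    )


def orientation_null_zero_discovery(
    n_reps: int = 100,
    cohort_seed: int = 1,
    seed: int = 1_000,
    q_cut: float = 0.05,
    n_sites: int = 32_592,
    tss_weight: float = 0.5,
    window: int = 12_587,
    min_sites: int = 3,
) -> tuple[int, int, int]:
    """Strand-randomisation null of the orientation-bias battery.

    Emulates the near-baseline vector experiment: an unselected,
    TSS-preferential cohort of ``n_sites`` integrations (no drivers, no
    clonal selection) is clustered with the fixed-window rule (>=
    ``min_sites`` sites within ``window`` nt).  Clustering ignores
    strand, so each rep re-draws every site's strand fair-coin and
    re-runs the full Fisher+BH battery over all clusters.  Returns
    (reps with zero q < q_cut discoveries, total reps, n_clusters).
    """
    from .cis_detection import cluster_window
    from .synthetic_data import SimConfig

    n_samples = 8
    cfg = SimConfig(
        seed=cohort_seed,
        n_samples=n_samples,
        background_sites_per_sample=n_sites // n_samples,
        tss_weight=tss_weight,
        tss_decay=5_000.0,
        n_genes=20_000,
    )
    cohort, _ = simulate_cohort(cfg)
    clusters = cluster_window(cohort, window=window, min_sites=min_sites)
    member_lists = [c.member_index for c in clusters]
    n_in = np.array([len(m) for m in member_lists])
    rng = np.random.default_rng(seed)
    n_total = len(cohort)
    zero = 0
    for _ in range(n_reps):
        fwd = rng.random(n_total) < 0.5
        fwd_in = np.array([int(fwd[m].sum()) for m in member_lists])
        p = orientation_pvalues_vectorised(fwd_in, n_in, int(fwd.sum()), n_total)
        q = bh_adjust(p)
        if not (q < q_cut).any():
            zero += 1
    return zero, n_reps, len(clusters)


def saturation_signature(
    genome: GenomeModel,
    config: GkcConfig,
    thresholds: Optional[dict[float, float]],
    cohort_seed: int = 3,
    curve_seed: int = 11,
    n_driver_samples: int = 15,
    gain_at: int = 20,
    max_combos: int = 1_000,
) -> dict:
    """Saturation of a cohort whose drivers all sit in the first samples.

    Drivers are restricted to the first ``n_driver_samples`` tumours, so
    the CIS-bearing genome is exhausted early; the real coverage curve's
    marginal gain at ``gain_at`` samples is compared with the uniform
    random control's.
    """
    base = default_screen_config(seed=cohort_seed)
    genotypes = tuple(
        ["early"] * n_driver_samples + ["late"] * (base.n_samples - n_driver_samples)
    )
    drivers = tuple(replace(d, genotypes=("early",)) for d in base.drivers)
    cfg = replace(base, genotypes=genotypes, drivers=drivers)
    cohort, _ = simulate_cohort(cfg)
    cohort = merge_sites(cohort)
    if thresholds is None:
        thresholds = null_thresholds(len(cohort), genome, config)
    cis = call_cis(cohort, genome, config, thresholds=thresholds)
    member_rows = (
        np.unique(np.concatenate([c.member_index for c in cis])) if cis else np.array([], int)
    )
    subset = cohort.iloc[member_rows]
    samples = {
        sid: subset[subset["sample_id"] == sid].reset_index(drop=True)
        for sid in cohort["sample_id"].unique()
    }
    real = coverage_curve(samples, genome, max_combos=max_combos, seed=curve_seed)
    ctrl = random_control(samples, genome, max_combos=max_combos, seed=curve_seed)
    g_real = marginal_gain(real, gain_at)
    g_ctrl = marginal_gain(ctrl, gain_at)
    return {
        "n_cis": len(cis),
        "n_member_sites": int(len(subset)),
        "real_gain": g_real,
        "control_gain": g_ctrl,
        "gain_ratio": g_real / g_ctrl,
        "real_curve": real,
        "control_curve": ctrl,
    }
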