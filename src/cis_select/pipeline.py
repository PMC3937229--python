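"""End-to-end orchestration: simulate/load -> merge -> call -> test -> report.

One YAML config, one top-level seed, one machine-readable report.  Every
stage draws its randomness from a sub-seed derived from the top-level
seed, so two runs with equal configs produce identical report bodies
(timestamps are kept outside the body).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import cis_detection, io_formats, ris_processing, saturation, selection_stats
from .core import CIS, GenomeModel, ValidationError, mm9_like_genome
from .synthetic_data import SimConfig, DriverSpec, build_genome, default_screen_config, simulate_cohort

KNOWN_STAGES = ("simulate", "merge", "call_cis", "orient", "saturate", "rank")


class ConfigError(ValueError):
    """Pipeline config violates the documented schema; message names the field."""


class DependencyError(RuntimeError):
    """A stage was requested without its upstream artefact."""


def _sub_seed(seed: int, stage: str) -> np.random.SeedSequence:
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.SeedSequence([int(seed), tag])


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def report_rank_table(cohort: pd.DataFrame, cis_list: Sequence[CIS], top_n: int = 25) -> pd.DataFrame:
    """Most frequently targeted CISs ranked by number of member RISs.

    Ties break by higher mean reads/RIS, then by coordinate.  Columns are
    recomputed from the member lists.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    rows = []
    for c in cis_list:
        n_ins, n_samp, mean_reads = ris_processing.reads_per_ris_summary(c, cohort)
        rows.append((c.chrom, c.start, c.end, n_ins, n_samp, mean_reads))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_insertions", "n_samples", "mean_reads"]
    )
    df = df.sort_values(
        ["n_insertions", "mean_reads", "chrom", "start"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df.head(top_n)


def _load_config(config: Union[str, Path, Mapping[str, Any]]) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ConfigError("config must be a mapping")
    cfg = dict(config)
    if "seed" not in cfg:
        raise ConfigError("missing required field: seed")
    stages = cfg.get("stages")
    if not stages:
        raise ConfigError("missing required field: stages")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown} (known: {list(KNOWN_STAGES)})")
    return cfg


def _sim_config(cfg: dict, seed: int) -> SimConfig:
    sim = dict(cfg.get("simulate") or {})
    if sim.pop("reference_screen", True):
        base = default_screen_config(seed=seed)
        allowed = {"n_samples", "background_sites_per_sample", "tss_weight", "tss_decay", "n_genes"}
        bad = set(sim) - allowed
        if bad:
            raise ConfigError(f"simulate: unknown override fields {sorted(bad)}")
        if sim:
            d = {**asdict_config(base), **sim}
            if "n_samples" in sim:
                d["genotypes"] = None  # re-derive one label per sample
            base = SimConfig(**d)
        return base
    raise ConfigError("simulate: only reference_screen configs are supported in pipeline runs")


def asdict_config(c: SimConfig) -> dict:
    d = asdict(c)
    d["drivers"] = tuple(DriverSpec(**dd) for dd in d["drivers"])
    return d


def run_pipeline(
    config: Union[str, Path, Mapping[str, Any]],
    out_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Execute the requested stages in dependency order and return the report.

    The report body (everything except ``meta.timestamp``) is a pure
    function of the config; TSV sidecars are written under ``out_dir``
    when given.
    """
    cfg = _load_config(config)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    out = Path(out_dir or cfg.get("out_dir") or ".")
    out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {"config_seed": seed, "stages": {}}
    cohort: Optional[pd.DataFrame] = None
    genome: Optional[GenomeModel] = None
    truth = None
    cis_list: Optional[list[CIS]] = None

    if "simulate" in stages:
        sim_cfg = _sim_config(cfg, seed)
        cohort, truth = simulate_cohort(sim_cfg)
        genome = build_genome(sim_cfg)
        report["stages"]["simulate"] = {
            "n_samples": sim_cfg.n_samples,
            "n_sites": int(len(cohort)),
            "n_drivers": len(sim_cfg.drivers),
            "cohort_digest": _digest(cohort),
        }
        io_formats.write_ris_bed(cohort, out / "cohort.bed")
        truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
    elif "input_bed" in cfg:
        genome = mm9_like_genome()
        cohort = io_formats.read_ris_bed(cfg["input_bed"], genome)
        report["stages"]["load"] = {"n_sites": int(len(cohort)), "cohort_digest": _digest(cohort)}

    if "merge" in stages:
        if cohort is None:
            raise DependencyError("merge requires a simulated or loaded cohort")
        m = dict(cfg.get("merge") or {})
        cohort = ris_processing.merge_sites(
            cohort, max_gap=int(m.get("max_gap", 3)), ignore_strand=bool(m.get("ignore_strand", False))
        )
        report["stages"]["merge"] = {"n_sites": int(len(cohort)), "cohort_digest": _digest(cohort)}

    if "call_cis" in stages:
        if cohort is None or genome is None:
            raise DependencyError("call_cis requires a cohort")
        c = dict(cfg.get("call_cis") or {})
        gkc = cis_detection.GkcConfig(
            scales=tuple(c.get("scales", cis_detection.DEFAULT_SCALES)),
            alpha=float(c.get("alpha", 0.05)),
            n_null=int(c.get("n_null", 100)),
            grid_step=float(c.get("grid_step", 0.25)),
            seed=int(_sub_seed(seed, "call_cis").generate_state(1)[0] % (2**31)),
        )
        cis_list = cis_detection.call_cis(cohort, genome, gkc)
        table = io_formats.cis_table(cis_list)
        table.to_csv(out / "cis.tsv", sep="\t", index=False)
        report["stages"]["call_cis"] = {
            "n_cis": len(cis_list),
            "scales": list(gkc.scales),
            "alpha": gkc.alpha,
            "n_null": gkc.n_null,
            "null_seed": gkc.seed,
        }

    if "orient" in stages:
        if cis_list is None or cohort is None:
            raise DependencyError("orient requires called CISs")
        o = dict(cfg.get("orient") or {})
        results = selection_stats.orientation_test_all(cis_list, cohort)
        biased = selection_stats.biased_cis_set(results, q_cut=float(o.get("q_cut", 0.05)))
        selection_stats.orientation_table(results).to_csv(out / "orientation.tsv", sep="\t", index=False)
        report["stages"]["orient"] = {
            "n_tested": len(results),
            "n_biased": len(biased),
            "q_cut": float(o.get("q_cut", 0.05)),
        }

    if "saturate" in stages:
        if cohort is None or genome is None:
            raise DependencyError("saturate requires a cohort")
        s = dict(cfg.get("saturate") or {})
        if s.get("cis_members_only", True):
            if cis_list is None:
                raise DependencyError("saturate with cis_members_only requires called CISs")
            member_rows = np.unique(np.concatenate([c.member_index for c in cis_list])) if cis_list else np.array([], int)
            subset = cohort.iloc[member_rows]
        else:
            subset = cohort
        samples = saturation.split_by_sample(subset)
        sat_seed = int(_sub_seed(seed, "saturate").generate_state(1)[0] % (2**31))
        kw = dict(
            half_width=int(s.get("half_width", 7_500)),
            max_combos=int(s.get("max_combos", 1_000)),
            seed=sat_seed,
        )
        real = saturation.coverage_curve(samples, genome, **kw)
        ctrl = saturation.random_control(samples, genome, **kw)
        both = pd.concat(
            [real.table.assign(label="real"), ctrl.table.assign(label="random_control")]
        )
        both.to_csv(out / "saturation.tsv", sep="\t", index=False)
        report["stages"]["saturate"] = {
            "n_samples": len(samples),
            "seed": sat_seed,
            "real_final_median": float(real.table["median"].iloc[-1]),
            "control_final_median": float(ctrl.table["median"].iloc[-1]),
        }

    if "rank" in stages:
        if cis_list is None or cohort is None:
            raise DependencyError("rank requires called CISs")
        top_n = int((cfg.get("rank") or {}).get("top_n", 25))
        table = report_rank_table(cohort, cis_list, top_n=top_n)
        table.to_csv(out / "rank.tsv", sep="\t", index=False)
        report["stages"]["rank"] = {"top_n": top_n, "rows": len(table)}

    meta = {"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    full = {"meta": meta, **report}
    with open(out / "report.json", "w") as fh:
        json.dump(full, fh, indent=2, sort_keys=True)
    return full
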