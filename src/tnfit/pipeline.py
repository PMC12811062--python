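"""Pipeline orchestration: config-driven runs and the run manifest.

A run either loads existing count tables + sample metadata or simulates a
library, then scores fitness and applies the filter cascade, writing every
intermediate as TSV plus a JSON manifest that summarizes inputs, seeds,
read totals and stage counts. Identical config + seed produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .cascade import CascadeReport, FilterConfig, run_cascade, write_cascade_report
from .fitness import (
    fitness_table,
    read_fitness_table,
    write_fitness_table,
)
from .io import CountTable, ValidationError, read_count_table, write_count_table
from .samples import SampleMeta, read_sample_meta, write_sample_meta
from .synthetic import make_library, simulate_experiment, write_ground_truth


def summarize_reads(meta: Sequence[SampleMeta] | Sequence[int]) -> tuple[int, int, int]:
    """(min, mean, max) of mapped-read totals; mean rounded half away from zero.

    Accepts SampleMeta records or bare integers.
    """
    totals = [m.mapped_reads if isinstance(m, SampleMeta) else int(m) for m in meta]
    if not totals:
        raise ValidationError("summarize_reads needs at least one sample")
    mean = sum(totals) / len(totals)
    rounded = int(math.floor(mean + 0.5)) if mean >= 0 else -int(math.floor(-mean + 0.5))
    return min(totals), rounded, max(totals)


@dataclass
class RunManifest:
    """Reproducibility record written at the end of every pipeline run."""

    config: dict
    seed: int | None
    input_digests: dict[str, str]
    mapped_reads: dict[str, int]
    reads_min: int
    reads_mean: int
    reads_max: int
    stage_counts: dict[str, int]
    parallel_counts: dict[str, int]
    version: str = __version__

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "rt", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def filter_config_from_mapping(cfg: Mapping) -> FilterConfig:
    kwargs = {}
    if "baseline_condition" in cfg:
        kwargs["baseline_condition"] = str(cfg["baseline_condition"])
    if "neutral_band" in cfg:
        lo, hi = cfg["neutral_band"]
        kwargs["neutral_band"] = (float(lo), float(hi))
    if "max_replicate_distance" in cfg:
        kwargs["max_replicate_distance"] = float(cfg["max_replicate_distance"])
    if "difference_thresholds" in cfg:
        kwargs["difference_thresholds"] = tuple(
            float(t) for t in cfg["difference_thresholds"]
        )
    if "min_t1_count" in cfg:
        kwargs["min_t1_count"] = float(cfg["min_t1_count"])
    return FilterConfig(**kwargs)


def run_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """Execute simulate-or-load -> fitness -> cascade, writing all artifacts.

    ``config`` either contains a ``simulate`` section (library and experiment
    parameters) or an ``inputs`` section naming t1/t2 count tables and a
    sample-metadata TSV. The manifest is written last, so its presence marks
    a completed run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    input_digests: dict[str, str] = {}

    if "simulate" in config:
        sim = dict(config["simulate"])
        lib = make_library(
            n_genes=int(sim.get("n_genes", 5000)),
            frac_deleterious=float(sim.get("frac_deleterious", 0.1)),
            deleterious_fitness_range=tuple(
                sim.get("deleterious_fitness_range", (0.0, 0.6))
            ),
            abundance_dispersion=float(sim.get("abundance_dispersion", 1.4)),
            background_expansion=float(sim.get("background_expansion", 121.1)),
            seed=int(seed if seed is not None else 0),
        )
        conditions = list(
            sim.get("conditions", ["sucrose", "acetate", "succinate", "glycerol"])
        )
        t1, t2, meta = simulate_experiment(
            lib,
            conditions=conditions,
            replicates=int(sim.get("replicates", 2)),
            depth=int(sim.get("depth", 2_000_000)),
            seed=int(seed if seed is not None else 0),
        )
        write_count_table(t1, outdir / "t1_counts.tsv")
        write_count_table(t2, outdir / "t2_counts.tsv")
        write_sample_meta(meta, outdir / "sample_meta.tsv")
        with open(outdir / "ground_truth.tsv", "wt", encoding="utf-8") as fh:
            write_ground_truth(lib, fh)
    elif "inputs" in config:
        inputs = config["inputs"]
        paths = {key: Path(inputs[key]) for key in ("t1", "t2", "meta")}
        for key, path in paths.items():
            if not path.exists():
                raise FileNotFoundError(f"input {key!r} not found: {path}")
            input_digests[str(path)] = _sha256(path)
        t1 = read_count_table(paths["t1"])
        t2 = read_count_table(paths["t2"])
        meta = read_sample_meta(paths["meta"])
    else:
        raise ValidationError("config needs a 'simulate' or 'inputs' section")

    fit_cfg = config.get("fitness", {})
    records = fitness_table(
        t1, t2, meta, min_t1_count=float(fit_cfg.get("min_t1_count", 50.0))
    )
    write_fitness_table(records, outdir / "fitness.tsv")

    cascade_cfg = filter_config_from_mapping(config.get("cascade", {}))
    report = run_cascade(records, cascade_cfg)
    write_cascade_report(report, outdir / "cascade")

    t2_meta = [m for m in meta if m.timepoint == "t2"]
    lo, mean, hi = summarize_reads(t2_meta)
    manifest = RunManifest(
        config=config,
        seed=seed,
        input_digests=input_digests,
        mapped_reads={m.sample_id: m.mapped_reads for m in t2_meta},
        reads_min=lo,
        reads_mean=mean,
        reads_max=hi,
        stage_counts=dict(report.stage_counts),
        parallel_counts=dict(report.parallel_counts),
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def load_cascade_inputs(fitness_path: str | Path):
    """Read a fitness TSV (ours or an external per-gene table) for the cascade."""
    path = Path(fitness_path)
    if not path.exists():
        raise FileNotFoundError(f"fitness table not found: {path}")
    return read_fitness_table(path)


__all__ = [
    "CascadeReport",
    "RunManifest",
    "filter_config_from_mapping",
    "load_cascade_inputs",
    "load_config",
    "run_pipeline",
    "summarize_reads",
]
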