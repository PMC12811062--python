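"""Gene-selection cascade: from a fitness table to substrate-specific genes.

The cascade reproduces the screen's selection logic. Starting from all
scored genes it applies, in order:

1. completeness — drop genes with a zero-count flag or low-t1 flag in any
   condition (zeros are categorical, not numerical, information);
2. baseline neutrality — keep genes whose mean fitness on the baseline
   carbon source lies in a closed neutral band (default [0.9, 1.1]:
   "loss does not affect growth on sucrose");
3. replicate concordance — keep genes whose duplicate flasks agree to
   better than a strict distance (default < 0.2) in every challenge
   condition. Neutrality and concordance are reported as parallel counts
   on the completeness survivors; their intersection is carried forward;
4. differential classification — at each threshold theta, a gene is
   differential on substrate s when |mean_w(s) - mean_w(baseline)| > theta,
   and substrate-specific when it is differential on exactly one substrate.

Survivor counts are non-increasing along the chain, and differential sets
at a larger threshold nest inside those at a smaller one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .fitness import FitnessRecord
from .io import ValidationError

DEFAULT_BASELINE = "sucrose"
DEFAULT_NEUTRAL_BAND = (0.9, 1.1)
DEFAULT_MAX_REPLICATE_DISTANCE = 0.2
DEFAULT_DIFFERENCE_THRESHOLDS = (0.2, 0.3, 0.4)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the selection cascade."""

    baseline_condition: str = DEFAULT_BASELINE
    neutral_band: tuple[float, float] = DEFAULT_NEUTRAL_BAND
    max_replicate_distance: float = DEFAULT_MAX_REPLICATE_DISTANCE
    difference_thresholds: tuple[float, ...] = DEFAULT_DIFFERENCE_THRESHOLDS
    min_t1_count: float = 50.0

    def __post_init__(self) -> None:
        lo, hi = self.neutral_band
        if lo > hi:
            raise ValidationError(f"neutral_band lower > upper: {self.neutral_band}")
        thresholds = tuple(self.difference_thresholds)
        if any(t <= 0 for t in thresholds):
            raise ValidationError("difference thresholds must be positive")
        if list(thresholds) != sorted(set(thresholds)):
            raise ValidationError("difference thresholds must be strictly increasing")
        object.__setattr__(self, "difference_thresholds", thresholds)
        object.__setattr__(self, "neutral_band", (float(lo), float(hi)))


class _Index:
    """(gene, condition) lookup over a fitness table."""

    def __init__(self, table: Sequence[FitnessRecord]):
        self.by_key: dict[tuple[str, str], FitnessRecord] = {}
        seen_genes: dict[str, None] = {}
        seen_conds: dict[str, None] = {}
        for rec in table:
            key = (rec.gene_id, rec.condition)
            if key in self.by_key:
                raise ValidationError(f"duplicate record for {key}")
            self.by_key[key] = rec
            seen_genes.setdefault(rec.gene_id)
            seen_conds.setdefault(rec.condition)
        self.genes = list(seen_genes)
        self.conditions = list(seen_conds)

    def get(self, gene: str, condition: str) -> FitnessRecord | None:
        return self.by_key.get((gene, condition))

    def require_conditions(self, conditions: Iterable[str]) -> None:
        missing = [c for c in conditions if c not in self.conditions]
        if missing:
            raise ValidationError(f"conditions absent from fitness table: {missing}")


def completeness_filter(
    table: Sequence[FitnessRecord], conditions: Sequence[str]
) -> set[str]:
    """Genes free of zero-count and low-t1 flags in every listed condition."""
    idx = _Index(table)
    idx.require_conditions(conditions)
    retained = set()
    for gene in idx.genes:
        recs = [idx.get(gene, c) for c in conditions]
        if all(r is not None and not r.flag_zero and not r.flag_low_t1 for r in recs):
            retained.add(gene)
    return retained


def neutral_on_baseline(
    table: Sequence[FitnessRecord], genes: set[str], cfg: FilterConfig
) -> set[str]:
    """Genes whose baseline mean fitness lies in the closed neutral band."""
    idx = _Index(table)
    idx.require_conditions([cfg.baseline_condition])
    lo, hi = cfg.neutral_band
    out = set()
    for gene in genes:
        rec = idx.get(gene, cfg.baseline_condition)
        if rec is not None and rec.mean_w is not None and lo <= rec.mean_w <= hi:
            out.add(gene)
    return out


def concordance_filter(
    table: Sequence[FitnessRecord],
    genes: set[str],
    cfg: FilterConfig,
    conditions: Sequence[str] | None = None,
) -> set[str]:
    """Genes with replicate distance strictly below the cap in every
    challenge (non-baseline) condition under comparison."""
    idx = _Index(table)
    if conditions is None:
        conditions = [c for c in idx.conditions if c != cfg.baseline_condition]
    idx.require_conditions(conditions)
    out = set()
    for gene in genes:
        ok = True
        for cond in conditions:
            rec = idx.get(gene, cond)
            if (
                rec is None
                or rec.replicate_distance is None
                or not rec.replicate_distance < cfg.max_replicate_distance
            ):
                ok = False
                break
        if ok:
            out.add(gene)
    return out


class DifferentialResult(NamedTuple):
    by_substrate: dict[str, set[str]]
    union: set[str]


def differential_genes(
    table: Sequence[FitnessRecord],
    genes: set[str],
    cfg: FilterConfig,
    threshold: float,
    substrates: Sequence[str] | None = None,
) -> DifferentialResult:
    """Genes whose mean fitness differs from baseline by more than
    ``threshold`` (strict), per substrate, plus the union across substrates."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    idx = _Index(table)
    if substrates is None:
        substrates = [c for c in idx.conditions if c != cfg.baseline_condition]
    idx.require_conditions(list(substrates) + [cfg.baseline_condition])
    by_substrate: dict[str, set[str]] = {s: set() for s in substrates}
    for gene in genes:
        base = idx.get(gene, cfg.baseline_condition)
        if base is None or base.mean_w is None:
            continue
        for sub in substrates:
            rec = idx.get(gene, sub)
            if rec is None or rec.mean_w is None:
                continue
            if abs(rec.mean_w - base.mean_w) > threshold:
                by_substrate[sub].add(gene)
    union = set().union(*by_substrate.values()) if by_substrate else set()
    return DifferentialResult(by_substrate, union)


def substrate_specific(differential: dict[str, set[str]]) -> dict[str, set[str]]:
    """Genes differential on exactly one substrate, per substrate."""
    out: dict[str, set[str]] = {}
    for sub, genes in differential.items():
        others = set().union(
            *(g for s, g in differential.items() if s != sub)
        ) if len(differential) > 1 else set()
        out[sub] = genes - others
    return out


@dataclass
class CascadeReport:
    """Every stage's survivor count and every classified gene set.

    ``stage_counts`` is the monotone chain (input, complete,
    neutral_and_concordant, then differential unions by rising threshold);
    the parallel neutral-band and concordance counts on the completeness
    survivors live in ``parallel_counts``.
    """

    stage_counts: dict[str, int]
    parallel_counts: dict[str, int]
    differential_sets: dict[tuple[str, float], frozenset[str]]
    union_differential: dict[float, frozenset[str]]
    specific_sets: dict[tuple[str, float], frozenset[str]]
    baseline_condition: str
    substrates: tuple[str, ...]
    core_genes: frozenset[str] = field(default_factory=frozenset)


def run_cascade(
    table: Sequence[FitnessRecord],
    cfg: FilterConfig | None = None,
    conditions: Sequence[str] | None = None,
) -> CascadeReport:
    """Apply the full selection cascade to a fitness table."""
    cfg = cfg or FilterConfig()
    idx = _Index(table)
    if conditions is None:
        conditions = list(idx.conditions)
    if cfg.baseline_condition not in conditions:
        raise ValidationError(
            f"baseline condition {cfg.baseline_condition!r} not in {list(conditions)}"
        )
    substrates = tuple(c for c in conditions if c != cfg.baseline_condition)

    complete = completeness_filter(table, conditions)
    neutral = neutral_on_baseline(table, complete, cfg)
    concordant = concordance_filter(table, complete, cfg, substrates)
    core = neutral & concordant

    stage_counts: dict[str, int] = {
        "input": len(idx.genes),
        "complete": len(complete),
        "neutral_and_concordant": len(core),
    }
    parallel_counts = {
        "neutral_on_baseline": len(neutral),
        "replicate_concordant": len(concordant),
    }
    differential_sets: dict[tuple[str, float], frozenset[str]] = {}
    union_differential: dict[float, frozenset[str]] = {}
    specific_sets: dict[tuple[str, float], frozenset[str]] = {}
    for theta in cfg.difference_thresholds:
        diff = differential_genes(table, core, cfg, theta, substrates)
        spec = substrate_specific(diff.by_substrate)
        union_differential[theta] = frozenset(diff.union)
        stage_counts[f"differential_gt_{theta:g}"] = len(diff.union)
        for sub in substrates:
            differential_sets[(sub, theta)] = frozenset(diff.by_substrate[sub])
            specific_sets[(sub, theta)] = frozenset(spec[sub])
    return CascadeReport(
        stage_counts=stage_counts,
        parallel_counts=parallel_counts,
        differential_sets=differential_sets,
        union_differential=union_differential,
        specific_sets=specific_sets,
        baseline_condition=cfg.baseline_condition,
        substrates=substrates,
        core_genes=frozenset(core),
    )


def write_cascade_report(report: CascadeReport, outdir: str | Path) -> None:
    """Serialize a report: stage table plus one gene list per (substrate, theta)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = pd.DataFrame(
        [("chain", k, v) for k, v in report.stage_counts.items()]
        + [("parallel", k, v) for k, v in report.parallel_counts.items()],
        columns=["kind", "stage", "genes"],
    )
    stages.to_csv(outdir / "stage_counts.tsv", sep="\t", index=False, lineterminator="\n")
    for (sub, theta), genes in report.differential_sets.items():
        _write_gene_list(outdir / f"differential_{sub}_gt{theta:g}.tsv", genes)
    for (sub, theta), genes in report.specific_sets.items():
        _write_gene_list(outdir / f"specific_{sub}_gt{theta:g}.tsv", genes)
    for theta, genes in report.union_differential.items():
        _write_gene_list(outdir / f"differential_any_gt{theta:g}.tsv", genes)


def _write_gene_list(path: Path, genes: frozenset[str]) -> None:
    pd.DataFrame({"gene_id": sorted(genes)}).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
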