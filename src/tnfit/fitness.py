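"""Competitive fitness W per gene, replicate and condition.

For a pooled mutant screen, gene i's fitness over the growth interval is

    W_i = ln(n_i,t2 * d / n_i,t1) / ln((1 - n_i,t2) * d / (1 - n_i,t1))

where n_i,t1 and n_i,t2 are the gene's read proportions at inoculation and
harvest and d is the population expansion factor (OD600_t2 / OD600_t1).
The numerator is the log fold-expansion of the mutant lineage, the
denominator that of the rest of the population; W = 1 is neutral, W = 0 a
lineage that did not grow at all.

Genes with a zero count in any relevant sample cannot be scored — a zero
says the lineage vanished at some unknown point within the interval, which
is categorical, not numerical, information — so zeros propagate as absence
plus a flag, never as a substituted number. Genes with low t1
representation (mean count <= 50 by default) are flagged as unscorable for
the same reason: they were never well measured at inoculation.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .io import CountTable, ParseError, ValidationError
from .samples import SampleMeta, read_sample_meta, write_sample_meta  # noqa: F401

DEFAULT_MIN_T1_COUNT = 50.0


class UndefinedFitnessError(ValueError):
    """Fitness is undefined (zero harvest proportion); caller must flag."""


class DegenerateSampleError(ValueError):
    """The reference population did not expand; W has a zero denominator."""


def expansion_factor(od_t1: float, od_t2: float) -> float:
    """Population expansion d = OD600_t2 / OD600_t1."""
    if od_t1 <= 0 or od_t2 <= 0:
        raise ValidationError(f"ODs must be positive, got ({od_t1}, {od_t2})")
    return od_t2 / od_t1


def proportions(counts: np.ndarray) -> np.ndarray:
    """Per-gene read proportions n_i = count_i / total for one sample."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("cannot compute proportions of an all-zero sample")
    return counts / total


def fitness_w(n_t1: float, n_t2: float, d: float) -> float:
    """Scalar fitness from t1/t2 proportions and the expansion factor.

    Raises :class:`UndefinedFitnessError` for a zero harvest proportion (the
    caller must flag the gene rather than receive a sentinel value) and
    :class:`DegenerateSampleError` when the rest of the population shows no
    net expansion (denominator log of 1).
    """
    if not 0.0 < n_t1 < 1.0:
        raise ValidationError(f"n_t1 must be in (0, 1), got {n_t1}")
    if n_t2 == 0.0:
        raise UndefinedFitnessError("harvest proportion is zero; fitness undefined")
    if not 0.0 < n_t2 < 1.0:
        raise ValidationError(f"n_t2 must be in (0, 1), got {n_t2}")
    denom_arg = (1.0 - n_t2) * d / (1.0 - n_t1)
    if denom_arg <= 0.0:
        raise ValidationError("denominator argument must be positive")
    denom = math.log(denom_arg)
    if denom == 0.0:
        raise DegenerateSampleError("reference population unexpanded; W undefined")
    return math.log(n_t2 * d / n_t1) / denom


def _w_vector(n1: np.ndarray, n2: np.ndarray, d: float) -> np.ndarray:
    # vectorized form of fitness_w; callers mask zeros beforehand
    return np.log(n2 * d / n1) / np.log((1.0 - n2) * d / (1.0 - n1))


@dataclass(frozen=True)
class FitnessRecord:
    """Per gene x condition fitness with replicate detail and exclusion flags.

    replicate_w holds one entry per replicate; an entry is None when that
    replicate could not be scored (zero count). mean_w and
    replicate_distance (max pairwise |difference|, i.e. |w1 - w2| for
    duplicates) are present only when every replicate is scored.
    """

    gene_id: str
    condition: str
    replicate_w: tuple[float | None, ...]
    mean_w: float | None
    replicate_distance: float | None
    flag_low_t1: bool
    flag_zero: bool


def _aggregate(values: Sequence[float | None]) -> tuple[float | None, float | None]:
    if any(v is None for v in values) or not values:
        return None, None
    vals = [float(v) for v in values]  # type: ignore[arg-type]
    mean = sum(vals) / len(vals)
    dist = max((abs(a - b) for a, b in itertools.combinations(vals, 2)), default=0.0)
    return mean, dist


def fitness_table(
    t1_counts: CountTable,
    t2_counts: CountTable,
    meta: Sequence[SampleMeta],
    min_t1_count: float = DEFAULT_MIN_T1_COUNT,
) -> list[FitnessRecord]:
    """Score every gene in every condition present in the t2 table.

    t1 proportions are computed from the pooled t1 samples against the full
    table total; each replicate's W uses that replicate's own expansion
    factor d from its SampleMeta. flag_low_t1 marks genes whose mean t1
    count is <= ``min_t1_count`` (strictly greater survives); flag_zero
    marks genes with a zero in any relevant sample, whose affected
    replicate_w entries are absent.
    """
    if t1_counts.gene_ids != t2_counts.gene_ids:
        raise ValidationError("t1 and t2 tables must share gene_ids in order")
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in t2_counts.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"no SampleMeta for t2 samples: {missing}")

    t1 = np.asarray(t1_counts.counts, dtype=float)
    pooled = t1.sum(axis=1)
    if pooled.sum() <= 0:
        raise ValidationError("t1 table has no reads")
    n1 = pooled / pooled.sum()
    mean_t1 = t1.mean(axis=1)
    low_t1 = mean_t1 <= min_t1_count
    t1_zero = (t1 == 0).any(axis=1)

    # group t2 samples by condition, replicates in replicate order
    cond_samples: dict[str, list[str]] = {}
    for sid in t2_counts.sample_ids:
        cond_samples.setdefault(by_id[sid].condition, []).append(sid)
    for sids in cond_samples.values():
        sids.sort(key=lambda s: by_id[s].replicate)

    genes = t1_counts.gene_ids
    records: list[FitnessRecord] = []
    for cond, sids in cond_samples.items():
        rep_w_cols: list[np.ndarray] = []
        rep_zero_cols: list[np.ndarray] = []
        for sid in sids:
            col = np.asarray(t2_counts.column(sid), dtype=float)
            zero = col == 0
            n2 = proportions(col)
            d = by_id[sid].d
            with np.errstate(divide="ignore", invalid="ignore"):
                w = _w_vector(n1, n2, d)
            rep_w_cols.append(w)
            rep_zero_cols.append(zero)
        any_zero = t1_zero | np.logical_or.reduce(rep_zero_cols)
        for g, gene in enumerate(genes):
            rep_w = tuple(
                None if (t1_zero[g] or rep_zero_cols[r][g]) else float(rep_w_cols[r][g])
                for r in range(len(sids))
            )
            mean_w, dist = _aggregate(rep_w)
            records.append(
                FitnessRecord(
                    gene_id=gene,
                    condition=cond,
                    replicate_w=rep_w,
                    mean_w=mean_w,
                    replicate_distance=dist,
                    flag_low_t1=bool(low_t1[g]),
                    flag_zero=bool(any_zero[g]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# TSV round-trip for fitness tables

def fitness_frame(records: Sequence[FitnessRecord]) -> pd.DataFrame:
    """Tabular view: gene_id, condition, w_rep*, mean_w, distance, flags."""
    n_rep = max((len(r.replicate_w) for r in records), default=0)
    rows = []
    for r in records:
        row: dict[str, object] = {"gene_id": r.gene_id, "condition": r.condition}
        for i in range(n_rep):
            w = r.replicate_w[i] if i < len(r.replicate_w) else None
            row[f"w_rep{i + 1}"] = np.nan if w is None else w
        row["mean_w"] = np.nan if r.mean_w is None else r.mean_w
        row["replicate_distance"] = (
            np.nan if r.replicate_distance is None else r.replicate_distance
        )
        row["flag_low_t1"] = r.flag_low_t1
        row["flag_zero"] = r.flag_zero
        rows.append(row)
    return pd.DataFrame(rows)


def write_fitness_table(
    records: Sequence[FitnessRecord], stream: IO[str] | str | os.PathLike
) -> None:
    fitness_frame(records).to_csv(
        stream, sep="\t", index=False, lineterminator="\n", float_format="%.6f"
    )


def read_fitness_table(stream: IO[str] | str | os.PathLike) -> list[FitnessRecord]:
    """Read a fitness TSV written by :func:`write_fitness_table`.

    Also accepts externally produced tables that provide at least gene_id,
    condition and either w_rep* columns or a mean_w column; missing flag
    columns default to False, a missing replicate_distance is recomputed
    from the replicate values when possible.
    """
    try:
        frame = pd.read_csv(stream, sep="\t")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"malformed fitness table: {exc}") from exc
    if not {"gene_id", "condition"}.issubset(frame.columns):
        raise ParseError("fitness table needs gene_id and condition columns")
    rep_cols = sorted(
        (c for c in frame.columns if c.startswith("w_rep")),
        key=lambda c: int(c[5:]),
    )
    records = []
    for row in frame.itertuples(index=False):
        rep_w = tuple(
            None if pd.isna(getattr(row, c)) else float(getattr(row, c))
            for c in rep_cols
        )
        agg_mean, agg_dist = _aggregate(rep_w) if rep_cols else (None, None)
        if "mean_w" in frame.columns:
            raw = getattr(row, "mean_w")
            mean_w = None if pd.isna(raw) else float(raw)
        else:
            mean_w = agg_mean
        if "replicate_distance" in frame.columns:
            raw = getattr(row, "replicate_distance")
            dist = None if pd.isna(raw) else float(raw)
        else:
            dist = agg_dist
        records.append(
            FitnessRecord(
                gene_id=str(row.gene_id),
                condition=str(row.condition),
                replicate_w=rep_w,
                mean_w=mean_w,
                replicate_distance=dist,
                flag_low_t1=bool(getattr(row, "flag_low_t1", False)),
                flag_zero=bool(getattr(row, "flag_zero", False)),
            )
        )
    return records
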