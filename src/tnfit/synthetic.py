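"""Synthetic transposon-library generator with known ground-truth fitness.

The generative model is the exact inverse of the competitive-fitness
estimator: over the growth interval a neutral lineage expands by a factor E
(the background expansion, ~7 generations in the experimental design this
emulates, E ~ 99-155), and a lineage with true fitness W expands by E**W.
Gene-level t2 proportions are the renormalized expanded masses; sequencing
is a multinomial draw at the requested depth. Because the estimator is the
algebraic inverse of this model, noise-free simulations recover true
fitness to machine precision, which makes recovery tests sharp.

t1 abundances are log-normal ("right-skewed") to emulate the uneven
insertion representation of a real library; the default dispersion (sigma
= 1.4) puts roughly 1-2% of a 5,000-gene library below a 50-count
threshold at 15M reads, exercising the low-count exclusion path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import CountTable, ValidationError
from .samples import SampleMeta

#: nominal per-sample read depth used to scale noise-free "counts"
NOISE_FREE_DEPTH = 15_000_000

#: default inoculation OD600; harvest OD is derived from the realized
#: expansion so the recorded OD ratio is exactly the d the estimator needs
DEFAULT_OD_T1 = 0.05


@dataclass(frozen=True)
class TrueLibrary:
    """Ground truth for a simulated library.

    true_fitness is per-gene W (1 = neutral, 0 = no growth); t1_abundance
    is a positive relative abundance, interpreted after normalization to
    proportions; background_expansion E > 1 is the fold-expansion of a
    neutral lineage over the growth interval.
    """

    gene_ids: tuple[str, ...]
    true_fitness: np.ndarray = field(repr=False)
    t1_abundance: np.ndarray = field(repr=False)
    background_expansion: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_fitness", np.asarray(self.true_fitness, dtype=float))
        object.__setattr__(self, "t1_abundance", np.asarray(self.t1_abundance, dtype=float))
        n = len(self.gene_ids)
        if self.true_fitness.shape != (n,) or self.t1_abundance.shape != (n,):
            raise ValidationError("fitness/abundance length must match gene_ids")
        if not np.all(np.isfinite(self.true_fitness)) or np.any(self.true_fitness < 0):
            raise ValidationError("true_fitness must be finite and >= 0")
        if np.any(self.t1_abundance <= 0):
            raise ValidationError("t1_abundance entries must be positive")
        if not self.background_expansion > 1:
            raise ValidationError("background_expansion must be > 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def t1_proportions(self) -> np.ndarray:
        return self.t1_abundance / self.t1_abundance.sum()


def make_library(
    n_genes: int,
    frac_deleterious: float = 0.1,
    deleterious_fitness_range: tuple[float, float] = (0.0, 0.6),
    abundance_dispersion: float = 1.4,
    background_expansion: float = 121.1,
    seed: int = 0,
) -> TrueLibrary:
    """Draw a library: a mostly-neutral fitness vector and skewed abundances.

    Exactly ``round(n_genes * frac_deleterious)`` genes (chosen uniformly at
    random) get fitness drawn uniformly from ``deleterious_fitness_range``;
    every other gene is exactly neutral (W = 1). Abundances are log-normal
    with sigma = ``abundance_dispersion``. Fully reproducible from ``seed``.
    """
    if n_genes < 2:
        raise ValidationError(f"n_genes must be >= 2, got {n_genes}")
    if not 0.0 <= frac_deleterious < 1.0:
        raise ValidationError(f"frac_deleterious must be in [0, 1), got {frac_deleterious}")
    if not background_expansion > 1:
        raise ValidationError("background_expansion must be > 1")
    lo, hi = deleterious_fitness_range
    if lo < 0 or hi < lo:
        raise ValidationError(f"bad deleterious_fitness_range {deleterious_fitness_range}")
    if abundance_dispersion <= 0:
        raise ValidationError("abundance_dispersion must be positive")

    rng = np.random.default_rng(seed)
    fitness = np.ones(n_genes)
    n_del = round(n_genes * frac_deleterious)
    if n_del:
        idx = rng.choice(n_genes, size=n_del, replace=False)
        fitness[idx] = rng.uniform(lo, hi, size=n_del)
    abundance = rng.lognormal(mean=0.0, sigma=abundance_dispersion, size=n_genes)
    width = len(str(n_genes - 1))
    gene_ids = tuple(f"gene_{i:0{width}d}" for i in range(n_genes))
    return TrueLibrary(
        gene_ids=gene_ids,
        true_fitness=fitness,
        t1_abundance=abundance,
        background_expansion=background_expansion,
        seed=seed,
    )


def expected_t2_proportions(lib: TrueLibrary) -> tuple[np.ndarray, float]:
    """Deterministic harvest-time proportions and realized total expansion.

    Gene i's unnormalized t2 mass is p1_i * E**W_i. The realized total
    expansion (the population-level d an OD measurement would report) is the
    abundance-weighted sum of those masses; it equals E only when every
    lineage is neutral.
    """
    p1 = lib.t1_proportions
    mass = p1 * lib.background_expansion ** lib.true_fitness
    total = float(mass.sum())
    return mass / total, total


def sample_counts(proportions: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Multinomial sequencing draw of ``depth`` reads over genes."""
    proportions = np.asarray(proportions, dtype=float)
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    if abs(proportions.sum() - 1.0) > 1e-8 or np.any(proportions < 0):
        raise ValidationError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, proportions / proportions.sum())


def simulate_experiment(
    lib: TrueLibrary,
    conditions: Sequence[str],
    replicates: int = 2,
    depth: int = NOISE_FREE_DEPTH,
    seed: int = 0,
    fitness_by_condition: Mapping[str, np.ndarray] | None = None,
    replicate_jitter: float = 0.05,
    od_t1: float = DEFAULT_OD_T1,
) -> tuple[CountTable, CountTable, list[SampleMeta]]:
    """Simulate a carbon-shift screen: one shared t1 sample, per-condition t2s.

    Each condition x replicate gets an independent t2 sample whose background
    expansion is jittered multiplicatively by up to ``replicate_jitter``
    (flask-to-flask variation); the realized total expansion of that flask is
    recorded in its SampleMeta as the OD ratio, exactly what the estimator's
    d should be. ``fitness_by_condition`` overrides the library's fitness
    vector per condition (for planting condition-specific effects); absent
    conditions use ``lib.true_fitness``.

    With ``depth=0`` the samples contain exact expected proportions scaled to
    :data:`NOISE_FREE_DEPTH` as real-valued "counts" (noise-free mode,
    intended for estimator-inversion tests).
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates}")
    if len(set(conditions)) != len(conditions):
        raise ValidationError(f"duplicate condition label in {list(conditions)}")
    if depth < 0:
        raise ValidationError("depth must be >= 0 (0 = noise-free mode)")
    if not 0.0 <= replicate_jitter < 1.0:
        raise ValidationError("replicate_jitter must be in [0, 1)")
    fitness_by_condition = dict(fitness_by_condition or {})
    for cond, w in fitness_by_condition.items():
        if np.asarray(w).shape != (lib.n_genes,):
            raise ValidationError(f"fitness override for {cond!r} has wrong length")

    rng = np.random.default_rng(seed)
    noise_free = depth == 0
    nominal = NOISE_FREE_DEPTH if noise_free else depth

    p1 = lib.t1_proportions
    # the child-seed / jitter stream is consumed identically in both modes,
    # so a depth=0 rerun at the same seed reproduces the same flasks exactly
    t1_seed = int(rng.integers(2**31))
    if noise_free:
        t1_counts = p1 * nominal
    else:
        t1_counts = sample_counts(p1, depth, seed=t1_seed)
    t1_table = CountTable(list(lib.gene_ids), ["t1"], t1_counts[:, None])
    meta = [
        SampleMeta(
            sample_id="t1", condition="library", nitrogen="urea", replicate=1,
            timepoint="t1", d=1.0, od_t1=od_t1, od_t2=od_t1, mapped_reads=nominal,
        )
    ]

    columns, sample_ids = [], []
    for cond in conditions:
        w_cond = np.asarray(fitness_by_condition.get(cond, lib.true_fitness), dtype=float)
        for rep in range(1, replicates + 1):
            jitter = float(rng.uniform(1 - replicate_jitter, 1 + replicate_jitter))
            flask = dataclasses.replace(
                lib,
                true_fitness=w_cond,
                background_expansion=lib.background_expansion * jitter,
            )
            p2, realized = expected_t2_proportions(flask)
            flask_seed = int(rng.integers(2**31))
            if noise_free:
                col = p2 * nominal
            else:
                col = sample_counts(p2, depth, seed=flask_seed)
            sample_id = f"{cond}_r{rep}"
            columns.append(col)
            sample_ids.append(sample_id)
            meta.append(
                SampleMeta(
                    sample_id=sample_id, condition=cond, nitrogen="diazotrophic",
                    replicate=rep, timepoint="t2", d=realized,
                    od_t1=od_t1, od_t2=od_t1 * realized, mapped_reads=nominal,
                )
            )
    t2_table = CountTable(list(lib.gene_ids), sample_ids, np.column_stack(columns))
    return t1_table, t2_table, meta


def write_ground_truth(lib: TrueLibrary, stream) -> None:
    """Write gene_id, true_fitness, t1_proportion as TSV for recovery scoring."""
    import pandas as pd

    pd.DataFrame(
        {
            "gene_id": lib.gene_ids,
            "true_fitness": lib.true_fitness,
            "t1_proportion": lib.t1_proportions,
        }
    ).to_csv(stream, sep="\t", index=False, lineterminator="\n")
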