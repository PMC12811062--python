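import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tnfit.fitness import FitnessRecord

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: the six harvest-sample mapped-read totals from the screen's published
#: cell-density table (acetate/succinate/glycerol, duplicate flasks)
TABLE1_MAPPED_READS = (
    15_001_388, 16_871_019, 17_650_273, 15_571_966, 18_910_633, 16_842_781,
)

CONDITIONS = ("sucrose", "acetate", "succinate", "glycerol")


def record(
    gene,
    condition,
    w1=1.0,
    w2=None,
    low=False,
    zero=False,
):
    """Build a consistent FitnessRecord from duplicate-flask W values.

    ``w2`` defaults to ``w1``; pass ``zero=True`` for an unscorable gene
    (replicate values absent).
    """
    if zero:
        return FitnessRecord(
            gene_id=gene, condition=condition, replicate_w=(None, None),
            mean_w=None, replicate_distance=None, flag_low_t1=low, flag_zero=True,
        )
    if w2 is None:
        w2 = w1
    return FitnessRecord(
        gene_id=gene, condition=condition, replicate_w=(w1, w2),
        mean_w=(w1 + w2) / 2, replicate_distance=abs(w1 - w2),
        flag_low_t1=low, flag_zero=False,
    )


def random_fitness_table(rng, n_genes=None, conditions=CONDITIONS):
    """A random but internally consistent fitness table for oracle tests."""
    if n_genes is None:
        n_genes = int(rng.integers(5, 51))
    table = []
    for g in range(n_genes):
        gene = f"g{g:03d}"
        for cond in conditions:
            if rng.random() < 0.08:
                table.append(record(gene, cond, zero=True, low=rng.random() < 0.3))
                continue
            mean = float(rng.normal(1.0, 0.35))
            delta = float(abs(rng.normal(0.0, 0.15)))
            table.append(
                record(
                    gene, cond, mean - delta / 2, mean + delta / 2,
                    low=rng.random() < 0.05,
                )
            )
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
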