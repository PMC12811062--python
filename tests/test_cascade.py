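"""Selection-cascade stages against brute-force re-scans and hand fixtures."""

import numpy as np
import pytest

from conftest import CONDITIONS, random_fitness_table, record
from tnfit.cascade import (
    FilterConfig,
    completeness_filter,
    concordance_filter,
    differential_genes,
    neutral_on_baseline,
    run_cascade,
    substrate_specific,
)
from tnfit.io import ValidationError

SUBSTRATES = [c for c in CONDITIONS if c != "sucrose"]


# ---------------------------------------------------------------------------
# Independent brute-force oracle: plain dict/loop re-implementation

def brute_force_cascade(table, cfg):
    recs = {(r.gene_id, r.condition): r for r in table}
    genes = sorted({r.gene_id for r in table})
    conditions = sorted({r.condition for r in table})
    substrates = [c for c in conditions if c != cfg.baseline_condition]

    complete = set()
    for g in genes:
        ok = True
        for c in conditions:
            r = recs.get((g, c))
            if r is None or r.flag_zero or r.flag_low_t1:
                ok = False
        if ok:
            complete.add(g)

    neutral = set()
    for g in complete:
        r = recs[(g, cfg.baseline_condition)]
        if r.mean_w is not None and cfg.neutral_band[0] <= r.mean_w <= cfg.neutral_band[1]:
            neutral.add(g)

    concordant = set()
    for g in complete:
        ok = True
        for c in substrates:
            r = recs[(g, c)]
            if r.replicate_distance is None or r.replicate_distance >= cfg.max_replicate_distance:
                ok = False
        if ok:
            concordant.add(g)

    core = neutral & concordant
    differential, specific = {}, {}
    for theta in cfg.difference_thresholds:
        for s in substrates:
            hits = set()
            for g in core:
                base, sub = recs[(g, cfg.baseline_condition)], recs[(g, s)]
                if base.mean_w is None or sub.mean_w is None:
                    continue
                if abs(sub.mean_w - base.mean_w) > theta:
                    hits.add(g)
            differential[(s, theta)] = hits
        for s in substrates:
            others = set()
            for s2 in substrates:
                if s2 != s:
                    others |= differential[(s2, theta)]
            specific[(s, theta)] = differential[(s, theta)] - others
    return complete, neutral, concordant, differential, specific


# ---------------------------------------------------------------------------

class TestStages:
    def test_completeness_drops_flagged(self):
        table = [record(f"g{i}", c) for i in range(5) for c in CONDITIONS]
        table[1] = record("g0", "acetate", zero=True)
        table[len(CONDITIONS) + 2] = record("g1", "succinate", zero=True)
        assert completeness_filter(table, CONDITIONS) == {"g2", "g3", "g4"}

    def test_completeness_all_clean(self):
        table = [record(f"g{i}", c) for i in range(4) for c in CONDITIONS]
        assert completeness_filter(table, CONDITIONS) == {"g0", "g1", "g2", "g3"}

    def test_completeness_missing_condition_rejected(self):
        with pytest.raises(ValidationError):
            completeness_filter([record("g0", "sucrose")], CONDITIONS)

    def test_neutral_band_is_closed(self):
        cfg = FilterConfig()
        table = [
            record("edge", "sucrose", 0.9),
            record("below", "sucrose", 0.89),
            record("upper", "sucrose", 1.1),
            record("above", "sucrose", 1.11),
        ]
        genes = {"edge", "below", "upper", "above"}
        assert neutral_on_baseline(table, genes, cfg) == {"edge", "upper"}

    def test_concordance_is_strict(self):
        cfg = FilterConfig()
        table = []
        for g, dist in [("at_cap", 0.2), ("under", 0.19)]:
            for c in CONDITIONS:
                table.append(record(g, c, 1.0 - dist / 2, 1.0 + dist / 2))
        got = concordance_filter(table, {"at_cap", "under"}, cfg, SUBSTRATES)
        assert got == {"under"}

    def test_differential_threshold_strict(self):
        cfg = FilterConfig()
        table = [
            record("hit", "sucrose", 1.0), record("hit", "acetate", 0.75),
            record("miss", "sucrose", 1.0), record("miss", "acetate", 0.85),
        ]
        diff = differential_genes(table, {"hit", "miss"}, cfg, 0.2, ["acetate"])
        assert diff.by_substrate["acetate"] == {"hit"}
        assert diff.union == {"hit"}

    def test_substrate_specific_definition(self):
        diff = {
            "acetate": {"only_a", "shared"},
            "succinate": {"shared"},
            "glycerol": set(),
        }
        spec = substrate_specific(diff)
        assert spec == {"acetate": {"only_a"}, "succinate": set(), "glycerol": set()}


class TestRunCascade:
    def hand_table(self):
        rows = []

        def add(gene, sucrose=1.0, acetate=1.0, succinate=1.0, glycerol=1.0):
            for cond, w in [("sucrose", sucrose), ("acetate", acetate),
                            ("succinate", succinate), ("glycerol", glycerol)]:
                rows.append(record(gene, cond, w))

        # eight genes exercising every exit path
        add("g1")                                   # clean, neutral, no difference
        rows.extend(record("g2", c, zero=(c == "acetate")) for c in CONDITIONS)
        rows.extend(record("g3", c, low=(c == "sucrose")) for c in CONDITIONS)
        add("g4", sucrose=0.85)                     # off the neutral band
        # g5: discordant replicates on glycerol
        for c in CONDITIONS:
            rows.append(record("g5", c, 0.85, 1.10) if c == "glycerol" else record("g5", c))
        add("g6", acetate=0.55)                     # acetate-specific, big effect
        add("g7", acetate=0.75, succinate=0.65)     # differential on two substrates
        add("g8", sucrose=0.9, acetate=0.9, succinate=0.9, glycerol=0.9)  # boundary
        return rows

    def test_hand_enumerated_stage_counts(self):
        report = run_cascade(self.hand_table(), FilterConfig())
        assert report.stage_counts == {
            "input": 8,
            "complete": 6,                       # g2, g3 flagged out
            "neutral_and_concordant": 4,         # g4 off-band, g5 discordant
            "differential_gt_0.2": 2,            # g6, g7
            "differential_gt_0.3": 2,            # g6, g7 (succinate 0.35)
            "differential_gt_0.4": 1,            # g6 only
        }
        assert report.parallel_counts == {
            "neutral_on_baseline": 5,            # g1, g5, g6, g7, g8
            "replicate_concordant": 5,           # g1, g4, g6, g7, g8
        }
        assert report.specific_sets[("acetate", 0.2)] == {"g6"}
        assert report.specific_sets[("acetate", 0.3)] == {"g6"}
        assert report.specific_sets[("succinate", 0.3)] == {"g7"}
        assert report.differential_sets[("acetate", 0.2)] == {"g6", "g7"}

    def test_all_neutral_noise_free_has_empty_differential_sets(self):
        from tnfit.fitness import fitness_table
        from tnfit.synthetic import make_library, simulate_experiment

        lib = make_library(30, frac_deleterious=0.0, seed=9)
        t1, t2, meta = simulate_experiment(lib, list(CONDITIONS), 2, depth=0, seed=9)
        report = run_cascade(fitness_table(t1, t2, meta, min_t1_count=0), FilterConfig())
        assert all(not s for s in report.differential_sets.values())
        assert report.stage_counts["neutral_and_concordant"] == 30

    def test_matches_brute_force_on_random_tables(self, rng):
        cfg = FilterConfig()
        for _ in range(60):
            table = random_fitness_table(rng)
            report = run_cascade(table, cfg)
            complete, neutral, concordant, diff, spec = brute_force_cascade(table, cfg)
            assert report.stage_counts["complete"] == len(complete)
            assert report.parallel_counts["neutral_on_baseline"] == len(neutral)
            assert report.parallel_counts["replicate_concordant"] == len(concordant)
            for key, genes in diff.items():
                assert report.differential_sets[key] == genes
            for key, genes in spec.items():
                assert report.specific_sets[key] == genes

    def test_subset_chain_and_threshold_nesting(self, rng):
        cfg = FilterConfig()
        for _ in range(40):
            report = run_cascade(random_fitness_table(rng), cfg)
            counts = list(report.stage_counts.values())
            assert counts == sorted(counts, reverse=True)
            for sub in report.substrates:
                assert (
                    report.differential_sets[(sub, 0.4)]
                    <= report.differential_sets[(sub, 0.3)]
                    <= report.differential_sets[(sub, 0.2)]
                )
                for theta in cfg.difference_thresholds:
                    assert (
                        report.specific_sets[(sub, theta)]
                        <= report.differential_sets[(sub, theta)]
                    )

    def test_missing_baseline_rejected(self):
        table = [record("g1", "acetate")]
        with pytest.raises(ValidationError):
            run_cascade(table, FilterConfig(baseline_condition="sucrose"))


class TestFilterConfig:
    def test_threshold_order_enforced(self):
        with pytest.raises(ValidationError):
            FilterConfig(difference_thresholds=(0.3, 0.2))

    def test_band_order_enforced(self):
        with pytest.raises(ValidationError):
            FilterConfig(neutral_band=(1.1, 0.9))
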