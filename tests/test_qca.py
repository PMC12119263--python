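"""QCA engine: necessity, truth table, minimization, solutions, metrics.

The minimizer is checked against an independent brute-force oracle that
enumerates all 3^k candidate implicants of small truth tables.
"""

import itertools

import numpy as np
import pytest

from qcascreen.calibration import FuzzyDataset
from qcascreen.errors import ConfigError, DataError, ValidationError
from qcascreen.qca import (
    Configuration,
    Implicant,
    TruthTable,
    TruthTableRow,
    build_truth_table,
    classify_core_peripheral,
    configuration_metrics,
    easy_counterfactuals,
    intermediate_minimize,
    minimize,
    necessity_analysis,
    prime_implicants,
    row_membership,
    run_fsqca,
)

# ---------------------------------------------------------------------------
# independent oracle: brute-force implicant enumeration


def brute_force_primes(k, onset, dontcares):
    """All prime implicants by exhaustive enumeration of 3^k candidates.

    The empty conjunction is inadmissible (a configuration must name at
    least one condition), so primality is judged against admissible
    generalizations only.
    """
    allowed_set = set(onset) | set(dontcares)

    def covered(mask, values):
        free = [j for j in range(k) if not (mask >> j) & 1]
        out = []
        for bits in itertools.product((0, 1), repeat=len(free)):
            c = values
            for j, b in zip(free, bits):
                c |= b << j
            out.append(c)
        return out

    def allowed(mask, values):
        return all(c in allowed_set for c in covered(mask, values))

    primes = set()
    for spec in itertools.product((None, 0, 1), repeat=k):
        mask = sum(1 << j for j, s in enumerate(spec) if s is not None)
        values = sum(1 << j for j, s in enumerate(spec) if s == 1)
        if mask == 0 or not allowed(mask, values):
            continue
        prime = True
        for j in range(k):
            gmask = mask & ~(1 << j)
            if (mask >> j) & 1 and gmask != 0 and allowed(gmask, values & ~(1 << j)):
                prime = False
                break
        if prime:
            primes.add((mask, values))
    return primes


def make_table(k, assignments):
    """TruthTable from a combo -> assignment mapping (counts/consistency dummy)."""
    rows = [
        TruthTableRow(c, 0 if assignments[c] == "remainder" else 10,
                      1.0 if assignments[c] == "positive" else 0.0, 0.0, assignments[c])
        for c in range(2**k)
    ]
    return TruthTable([f"c{j}" for j in range(k)], rows, 1, 0.8)


# ---------------------------------------------------------------------------


class TestNecessity:
    def test_identity_sets(self):
        x = np.array([0.2, 0.7, 0.9])
        fds = FuzzyDataset(np.arange(3), ["x"], x[:, None], x)
        res = {r.condition: r for r in necessity_analysis(fds)}
        assert res["x"].consistency == pytest.approx(1.0)
        assert res["x"].coverage == pytest.approx(1.0)
        assert res["x"].necessary

    def test_tautological_superset(self):
        y = np.array([0.3, 0.6, 0.9])
        fds = FuzzyDataset(np.arange(3), ["x"], np.ones((3, 1)), y)
        res = {r.condition: r for r in necessity_analysis(fds)}
        assert res["x"].consistency == pytest.approx(1.0)
        assert res["x"].coverage == pytest.approx(y.mean())

    def test_hand_arithmetic(self):
        x = np.array([0.8, 0.3, 0.9])
        y = np.array([0.6, 0.4, 0.9])
        fds = FuzzyDataset(np.arange(3), ["x"], x[:, None], y)
        res = {r.condition: r for r in necessity_analysis(fds)}
        assert res["x"].consistency == pytest.approx(1.8 / 1.9)
        assert res["x"].coverage == pytest.approx(1.8 / 2.0)

    def test_flag_rule_strict_at_point_nine(self):
        # consistency exactly 0.9 must not be flagged; above must be
        y = np.array([1.0, 1.0])
        x_exact = np.array([0.9, 0.9])
        fds = FuzzyDataset(np.arange(2), ["x"], x_exact[:, None], y)
        res = {r.condition: r for r in necessity_analysis(fds)}
        assert res["x"].consistency == pytest.approx(0.9)
        assert not res["x"].necessary
        x_above = np.array([0.95, 0.95])
        fds = FuzzyDataset(np.arange(2), ["x"], x_above[:, None], y)
        assert {r.condition: r for r in necessity_analysis(fds)}["x"].necessary

    def test_zero_outcome_rejected(self):
        fds = FuzzyDataset(np.arange(2), ["x"], np.array([[0.1], [0.2]]), np.zeros(2))
        with pytest.raises(DataError):
            necessity_analysis(fds)


class TestRowMembership:
    def test_min_rule(self):
        assert row_membership([0.7, 0.2], 0b01, 2) == pytest.approx(min(0.7, 0.8))

    def test_full_membership_and_annihilator(self):
        assert row_membership([1.0, 1.0], 0b11, 2) == 1.0
        assert row_membership([0.0, 0.9], 0b11, 2) == 0.0


class TestTruthTable:
    def test_partition(self, scored_cohort):
        from qcascreen import pipeline
        from qcascreen.calibration import calibrate_dataset

        specs = pipeline.default_calibration_specs(scored_cohort)[:3]
        fds = calibrate_dataset(scored_cohort, specs, "non_depression")
        tt = build_truth_table(fds, freq_threshold=1, cons_threshold=0.8)
        assert len(tt.rows) == 8
        assert sum(r.n_cases for r in tt.rows) == fds.n_cases

    def test_uniformly_positive_combo(self):
        rng = np.random.default_rng(3)
        m = np.clip(rng.uniform(0.55, 0.95, size=(50, 2)), 0, 1)
        fds = FuzzyDataset(np.arange(50), ["a", "b"], m, np.ones(50))
        tt = build_truth_table(fds, freq_threshold=1, cons_threshold=1.0)
        row = {r.combo: r for r in tt.rows}[0b11]
        assert row.n_cases == 50
        assert row.assignment == "positive"

    def test_hand_dataset_consistencies(self):
        # 12-case dataset; row consistencies recomputed by plain loops
        rng = np.random.default_rng(7)
        m = rng.uniform(0.05, 0.95, size=(12, 2))
        m[m == 0.5] += 0.001
        y = rng.uniform(0, 1, size=12)
        fds = FuzzyDataset(np.arange(12), ["a", "b"], m, y)
        tt = build_truth_table(fds, freq_threshold=1, cons_threshold=0.8)
        for row in tt.rows:
            num = den = 0.0
            for i in range(12):
                lits = [m[i, j] if (row.combo >> j) & 1 else 1 - m[i, j] for j in range(2)]
                mem = min(lits)
                num += min(mem, y[i])
                den += mem
            assert row.raw_consistency == pytest.approx(num / den)

    def test_half_membership_rejected(self):
        m = np.array([[0.5, 0.7]])
        fds = FuzzyDataset(np.arange(1), ["a", "b"], m, np.ones(1))
        with pytest.raises(ValidationError, match="adjust_half"):
            build_truth_table(fds)

    def test_threshold_monotonicity(self, scored_cohort):
        from qcascreen import pipeline
        from qcascreen.calibration import calibrate_dataset

        specs = pipeline.default_calibration_specs(scored_cohort)
        fds = calibrate_dataset(scored_cohort, specs, "non_depression")
        pos = None
        for thr in (0.80, 0.85, 0.90):
            tt = build_truth_table(fds, freq_threshold=10, cons_threshold=thr)
            now = set(tt.assigned("positive"))
            if pos is not None:
                assert now <= pos
            pos = now


class TestMinimize:
    def test_adjacent_rows_merge(self):
        # positives AB~C and ABC with all else negative -> implicant AB
        k = 3
        assignments = {c: "negative" for c in range(8)}
        assignments[0b011] = "positive"  # A, B present, C absent
        assignments[0b111] = "positive"
        res = minimize(make_table(k, assignments), "complex")
        assert [imp.label(["A", "B", "C"]) for imp in res.implicants] == ["A*B"]

    def test_single_positive_row_complex(self):
        assignments = {c: "negative" for c in range(8)}
        assignments[0b101] = "positive"
        res = minimize(make_table(3, assignments), "complex")
        assert [imp.label(["A", "B", "C"]) for imp in res.implicants] == ["A*~B*C"]

    def test_parsimonious_with_all_remainders(self):
        # one positive row, everything else a remainder -> single literal
        assignments = {c: "remainder" for c in range(8)}
        assignments[0b111] = "positive"
        res = minimize(make_table(3, assignments), "parsimonious")
        assert len(res.implicants) == 1
        assert res.implicants[0].n_literals() == 1

    def test_no_positive_rows_flagged_empty(self):
        assignments = {c: "negative" for c in range(4)}
        res = minimize(make_table(2, assignments), "complex")
        assert res.empty and res.implicants == []

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        assignments = {
            c: ["positive", "negative", "remainder"][rng.integers(0, 3)]
            for c in range(2**k)
        }
        if "positive" not in assignments.values():
            assignments[0] = "positive"
        table = make_table(k, assignments)
        positives = set(table.assigned("positive"))
        for mode in ("complex", "parsimonious"):
            dc = set(table.assigned("remainder")) if mode == "parsimonious" else set()
            res = minimize(table, mode)
            assert {(p.mask, p.values) for p in res.primes} == brute_force_primes(
                k, positives, dc
            )
            for cover in res.all_covers:
                covered = {c for imp in cover for c in imp.covered_combos()}
                assert positives <= covered
                allowed = positives | dc
                assert all(set(imp.covered_combos()) <= allowed for imp in cover)


class TestIntermediate:
    def test_all_either_equals_parsimonious(self):
        rng = np.random.default_rng(5)
        assignments = {
            c: ["positive", "negative", "remainder"][rng.integers(0, 3)] for c in range(16)
        }
        assignments[0] = "positive"
        table = make_table(4, assignments)
        pars = minimize(table, "parsimonious")
        inter = intermediate_minimize(table, {})
        assert inter.implicants == pars.implicants

    def test_no_remainders_equals_complex(self):
        assignments = {c: "positive" if c in (3, 7) else "negative" for c in range(8)}
        table = make_table(3, assignments)
        assert intermediate_minimize(table, {"c0": "present"}).implicants == minimize(
            table, "complex"
        ).implicants

    def test_hand_counterfactual_walk(self):
        # 8-row table: positive {A*B*C}, negatives {~A~B~C, A~B~C, ~AB~C},
        # remainders {AB~C, A~BC, ~ABC, ~A~BC}; expectation: A present only.
        assignments = {
            0b111: "positive",
            0b000: "negative", 0b001: "negative", 0b010: "negative",
            0b011: "remainder", 0b101: "remainder", 0b110: "remainder", 0b100: "remainder",
        }
        table = make_table(3, assignments)
        # easy: flips away from 111 must keep A=1 or move a free condition;
        # 011 (drop C) and 101 (drop B) are easy, 110/100 drop A -> hard
        easy = easy_counterfactuals(table, {"c0": "present"})
        assert easy == {0b011, 0b101}
        inter = intermediate_minimize(table, {"c0": "present"})
        labels = {imp.label(["A", "B", "C"]) for cover in inter.all_covers for imp in cover}
        # minimization over ON {111} with DC {011, 101}: primes A*B and A*C,
        # each a one-implicant cover; canonical cover is the lexicographic first
        assert labels == {"A*B", "A*C"}
        assert [imp.label(["A", "B", "C"]) for imp in inter.implicants] == ["A*B"]

    def test_contradictory_expectation_rejected(self):
        table = make_table(2, {0: "positive", 1: "negative", 2: "negative", 3: "remainder"})
        with pytest.raises(ConfigError):
            intermediate_minimize(table, {"c0": "sometimes"})


class TestCorePeripheral:
    def test_intermediate_equals_parsimonious_all_core(self):
        imp = Implicant(2, 0b11, 0b11)
        cfgs = classify_core_peripheral([imp], [imp], ["A", "B"])
        assert set(cfgs[0].roles.values()) == {"core-present"}

    def test_supporting_literal_peripheral(self):
        inter = Implicant(2, 0b11, 0b11)  # A*B
        pars = Implicant(2, 0b01, 0b01)  # A
        cfgs = classify_core_peripheral([inter], [pars], ["A", "B"])
        assert cfgs[0].roles == {"A": "core-present", "B": "peripheral-present"}

    def test_every_configuration_has_a_core_literal(self, scored_cohort):
        from qcascreen import pipeline
        from qcascreen.calibration import calibrate_dataset

        specs = pipeline.default_calibration_specs(scored_cohort)
        fds = calibrate_dataset(scored_cohort, specs, "non_depression")
        rep = run_fsqca(fds, 10, 0.85, pipeline.DEFAULT_EXPECTATIONS)
        for cfg in rep.intermediate.configurations:
            assert any(r.startswith("core") for r in cfg.roles.values())


class TestMetrics:
    def _fds(self):
        m = np.array([[0.8, 0.3], [0.4, 0.9], [0.6, 0.6]])
        y = np.array([0.7, 0.8, 0.4])
        return FuzzyDataset(np.arange(3), ["A", "B"], m, y)

    def test_single_configuration_unique_equals_raw(self):
        fds = self._fds()
        cfg = Configuration(Implicant(2, 0b01, 0b01), {})
        configuration_metrics([cfg], fds)
        assert cfg.unique_coverage == pytest.approx(cfg.raw_coverage)

    def test_identical_configurations_zero_unique(self):
        fds = self._fds()
        cfgs = [Configuration(Implicant(2, 0b01, 0b01), {}) for _ in range(2)]
        configuration_metrics(cfgs, fds)
        assert cfgs[0].unique_coverage == pytest.approx(0.0)
        assert cfgs[1].unique_coverage == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        fds = self._fds()
        cfg_a = Configuration(Implicant(2, 0b01, 0b01), {})  # membership = col A
        cfg_nb = Configuration(Implicant(2, 0b10, 0b00), {})  # membership = 1 - B
        sol_cons, sol_cov = configuration_metrics([cfg_a, cfg_nb], fds)
        # by hand: m_A = (.8,.4,.6): cons = (.7+.4+.4)/1.8, cov = 1.5/1.9
        assert cfg_a.consistency == pytest.approx(1.5 / 1.8)
        assert cfg_a.raw_coverage == pytest.approx(1.5 / 1.9)
        # m_~B = (.7,.1,.4): cons = (.7+.1+.4)/1.2, cov = 1.2/1.9
        assert cfg_nb.consistency == pytest.approx(1.2 / 1.2)
        # union = (.8,.4,.6): min with y = (.7,.4,.4)
        assert sol_cons == pytest.approx(1.5 / 1.8)
        assert sol_cov == pytest.approx(1.5 / 1.9)
        # unique coverages: union-without-A = m_~B covers 1.2/1.9
        assert cfg_a.unique_coverage == pytest.approx(1.5 / 1.9 - 1.2 / 1.9)
        assert cfg_nb.unique_coverage == pytest.approx(0.0)

    def test_bounds_and_unique_le_raw(self, scored_cohort):
        from qcascreen import pipeline
        from qcascreen.calibration import calibrate_dataset

        specs = pipeline.default_calibration_specs(scored_cohort)
        fds = calibrate_dataset(scored_cohort, specs, "non_anxiety")
        rep = run_fsqca(fds, 10, 0.80, pipeline.DEFAULT_EXPECTATIONS)
        for sol in (rep.complex, rep.parsimonious, rep.intermediate):
            if sol.empty:
                continue
            uniq_sum = 0.0
            for cfg in sol.configurations:
                assert 0 <= cfg.consistency <= 1
                assert 0 <= cfg.raw_coverage <= 1
                assert cfg.unique_coverage <= cfg.raw_coverage + 1e-12
                uniq_sum += cfg.unique_coverage
            assert uniq_sum <= sol.solution_coverage + 1e-12


class TestRunFsqca:
    def test_constant_positive_outcome(self):
        rng = np.random.default_rng(9)
        m = rng.uniform(0.05, 0.95, size=(200, 2))
        m[m == 0.5] += 0.001
        fds = FuzzyDataset(np.arange(200), ["a", "b"], m, np.ones(200))
        rep = run_fsqca(fds, freq_threshold=5, cons_threshold=0.8)
        frequent = [r.combo for r in rep.truth_table.rows if r.n_cases >= 5]
        assert set(rep.truth_table.assigned("positive")) == set(frequent)
        # with y identically 1, every configuration is perfectly consistent
        assert rep.intermediate.solution_consistency == pytest.approx(1.0)
        assert rep.intermediate.solution_coverage > 0.7

    def test_determinism(self, scored_cohort):
        from qcascreen import pipeline
        from qcascreen.calibration import calibrate_dataset

        specs = pipeline.default_calibration_specs(scored_cohort)
        fds = calibrate_dataset(scored_cohort, specs, "non_depression")
        r1 = run_fsqca(fds, 10, 0.85, pipeline.DEFAULT_EXPECTATIONS)
        r2 = run_fsqca(fds, 10, 0.85, pipeline.DEFAULT_EXPECTATIONS)
        assert [c.implicant for c in r1.intermediate.configurations] == [
            c.implicant for c in r2.intermediate.configurations
        ]
        assert r1.intermediate.solution_consistency == r2.intermediate.solution_consistency

    def test_planted_recipe_recovered(self):
        from qcascreen import cohort, pipeline, scales
        from qcascreen.calibration import calibrate_dataset

        recipe = cohort.PlantedRecipe(
            conditions={
                "marital": "present",
                "education": "present",
                "ssrs_total": "present",
            },
            outcome="non_depression",
        )
        cfg = cohort.CohortConfig(3000, seed=11, planted_recipes=[recipe])
        sc = scales.score_cohort(cohort.generate_cohort(cfg))
        specs = [
            s for s in pipeline.default_calibration_specs(sc)
            if s.variable in recipe.conditions
        ]
        fds = calibrate_dataset(sc, specs, "non_depression", case_id_col="case_id")
        rep = run_fsqca(fds, freq_threshold=10, cons_threshold=0.85)
        recipe_corner = 0b111
        hits = [
            c for c in rep.intermediate.configurations
            if c.implicant.covers(recipe_corner)
        ]
        assert hits, "no configuration covers the planted recipe"
        assert max(c.consistency for c in hits) > 0.9
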