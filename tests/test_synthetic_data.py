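import numpy as np
import pytest

from herbmine import (
    ArchetypeModel,
    ConstraintSet,
    DoseModel,
    InfeasibleConstraintsError,
    ValidationError,
    brute_force_support,
    check_constraints,
    fixture_archetypes,
    fixture_core7,
    fixture_table1,
    sample_dataset,
    solve_exact_transactions,
)
from herbmine.synthetic_data import (
    CORE7_COUNTS,
    read_constraints,
    write_constraints,
)


def _model(**kw):
    defaults = dict(
        archetypes=((frozenset({"AS", "LiC"}), 1.0),),
        dose_models={"AS": DoseModel(10, 2.5), "LiC": DoseModel(6.5, 1.75)},
        n=20,
        seed=0,
    )
    defaults.update(kw)
    return ArchetypeModel(**defaults)


class TestSampler:
    def test_single_archetype_gives_constant_composition(self):
        ds = sample_dataset(_model())
        assert ds.N == 20
        assert all(p.material_ids == {"AS", "LiC"} for p in ds.prescriptions)

    def test_identical_seed_gives_identical_dataset(self):
        a = sample_dataset(fixture_archetypes())
        b = sample_dataset(fixture_archetypes())
        assert a == b

    def test_different_seeds_differ(self):
        from dataclasses import replace
        a = sample_dataset(fixture_archetypes())
        b = sample_dataset(replace(fixture_archetypes(), seed=1))
        assert a != b

    def test_archetype_frequency_converges_at_binomial_rate(self):
        # two archetypes with p = 0.7 / 0.3; n = 10,000
        model = _model(
            archetypes=(
                (frozenset({"AS", "LiC"}), 7.0),
                (frozenset({"AS"}), 3.0),
            ),
            n=10_000,
            seed=5,
        )
        ds = sample_dataset(model)
        p = 0.7
        observed = sum(
            1 for rx in ds.prescriptions if rx.material_ids == {"AS", "LiC"}
        ) / model.n
        assert abs(observed - p) < 3 * np.sqrt(p * (1 - p) / model.n)

    def test_addon_inclusion_matches_probability(self):
        model = _model(
            addon_probs={"HP": 0.4},
            dose_models={"AS": DoseModel(10, 2.5), "LiC": DoseModel(6.5, 1.75),
                         "HP": DoseModel(15.12, 7.24)},
            n=10_000,
            seed=6,
        )
        ds = sample_dataset(model)
        observed = sum("HP" in rx.material_ids for rx in ds.prescriptions) / model.n
        assert abs(observed - 0.4) < 3 * np.sqrt(0.4 * 0.6 / model.n)

    def test_doses_respect_clip_floor(self):
        model = _model(dose_models={"AS": DoseModel(1.0, 5.0, min_clip=0.5),
                                    "LiC": DoseModel(6.5, 1.75)}, n=500)
        ds = sample_dataset(model)
        doses = [d for p in ds.prescriptions for m, d in p.items if m == "AS"]
        assert min(doses) >= 0.5

    def test_empty_archetype_list_rejected(self):
        with pytest.raises(ValidationError):
            ArchetypeModel(archetypes=())

    def test_missing_dose_model_rejected(self):
        with pytest.raises(ValidationError):
            sample_dataset(_model(dose_models={"AS": DoseModel(10, 2.5)}))


class TestChecker:
    def test_packaged_combination_counts_are_feasible(self):
        report = check_constraints(fixture_core7())
        assert report.feasible and not report.violations

    def test_singleton_marginals_make_core7_infeasible(self):
        cs = fixture_core7()
        augmented = ConstraintSet(
            universe=cs.universe,
            N=cs.N,
            constraints=cs.constraints + (
                (frozenset({"AS"}), 95),
                (frozenset({"LiC"}), 94),
                (frozenset({"RG"}), 78),
            ),
        )
        report = check_constraints(augmented)
        assert not report.feasible
        assert any("union bound" in v for v in report.violations)

    def test_monotonicity_breach_detected(self):
        cs = ConstraintSet(
            universe=("a", "b"), N=5,
            constraints=((frozenset("a"), 2), (frozenset("ab"), 3)),
        )
        report = check_constraints(cs)
        assert not report.feasible
        assert any("monotonicity" in v for v in report.violations)

    def test_empty_constraint_list_is_feasible(self):
        report = check_constraints(ConstraintSet(universe=("a",), N=5, constraints=()))
        assert report.feasible


class TestSolver:
    def test_core7_solution_matches_every_printed_count(self):
        ts = solve_exact_transactions(fixture_core7(), seed=0)
        assert ts.N == 99
        for itemset, count in CORE7_COUNTS:
            assert brute_force_support(ts, itemset) == count

    def test_single_constraint(self):
        cs = ConstraintSet(universe=("a",), N=5,
                           constraints=((frozenset("a"), 3),))
        ts = solve_exact_transactions(cs, seed=1)
        assert sum("a" in t for t in ts.transactions) == 3
        assert ts.N == 5

    def test_contradictory_constraints_raise(self):
        cs = ConstraintSet(
            universe=("a", "b"), N=5,
            constraints=((frozenset("a"), 2), (frozenset("ab"), 3)),
        )
        with pytest.raises(InfeasibleConstraintsError):
            solve_exact_transactions(cs, seed=0)

    def test_solver_is_deterministic_per_seed(self):
        a = solve_exact_transactions(fixture_core7(), seed=3)
        b = solve_exact_transactions(fixture_core7(), seed=3)
        assert a == b

    def test_solver_and_checker_agree_on_random_instances(self):
        # ground-truth sets perturbed at random: solve succeeds iff the
        # checker (exact integer search) declares the instance feasible
        rng = np.random.default_rng(11)
        universe = ("a", "b", "c", "d")
        for _ in range(40):
            n_trans = int(rng.integers(4, 12))
            truth = [
                frozenset(u for u in universe if rng.random() < 0.5)
                for _ in range(n_trans)
            ]
            sets = []
            for _ in range(int(rng.integers(1, 5))):
                size = int(rng.integers(1, 4))
                sets.append(frozenset(rng.choice(universe, size=size, replace=False)))
            constraints = []
            for s in set(sets):
                true_count = sum(1 for t in truth if s <= t)
                jitter = int(rng.integers(-1, 2))
                constraints.append((s, int(np.clip(true_count + jitter, 0, n_trans))))
            cs = ConstraintSet(universe=universe, N=n_trans,
                               constraints=tuple(constraints))
            report = check_constraints(cs)
            if report.feasible:
                ts = solve_exact_transactions(cs, seed=2)
                for s, k in constraints:
                    assert brute_force_support(ts, s) == k
            else:
                with pytest.raises(InfeasibleConstraintsError):
                    solve_exact_transactions(cs, seed=2)


class TestFixtures:
    def test_catalog_has_22_materials(self):
        assert len(fixture_table1()) == 22

    def test_core7_has_ten_constraints_at_n99(self):
        cs = fixture_core7()
        assert len(cs.constraints) == 10 and cs.N == 99

    def test_archetype_dose_models_carry_printed_values(self):
        model = fixture_archetypes()
        assert model.dose_models["HP"].mean == 15.12
        assert model.dose_models["HP"].sd == 7.24
        assert model.dose_models["ZJH"].mean == 25.18
        assert model.dose_models["OI"].mean == 3.09

    def test_constraint_file_roundtrip(self, tmp_path):
        cs = fixture_core7()
        path = write_constraints(cs, tmp_path / "core7.csv")
        again = read_constraints(path, universe=cs.universe)
        assert set(again.constraints) == set(cs.constraints)
        assert again.N == cs.N
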