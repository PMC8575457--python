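"""Genotype lattice: combinatorics, step classification, bootstrap epistasis."""

import math

import numpy as np
import pytest

from irtuning.landscape_epistasis import (
    EpistasisResult,
    Genotype,
    HypercubeSizeError,
    MissingGenotypeError,
    MutationSet,
    PhenotypeSample,
    enumerate_genotypes,
    enumerate_paths,
    epistasis_pairs,
    epistasis_test,
    run_landscape,
    step_test,
)
from irtuning.synthetic_data import ir75a_like_config, simulate_panel

THREE = MutationSet(("T289S", "Q536K", "F538L"))


class TestEnumeration:
    def test_three_mutations_give_eight_genotypes(self):
        genotypes = enumerate_genotypes(THREE)
        assert len(genotypes) == 8
        assert len({g.label for g in genotypes}) == 8
        assert genotypes == sorted(genotypes, key=lambda g: g.label)

    def test_single_mutation_gives_two(self):
        assert len(enumerate_genotypes(MutationSet(("A",)))) == 2

    def test_oversized_set_reports_magnitude(self):
        muts = MutationSet(tuple(f"M{i}" for i in range(114)))
        with pytest.raises(HypercubeSizeError, match=r"2\^114 = 2 x 10\^34"):
            enumerate_genotypes(muts)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_path_count_is_n_factorial(self, n):
        muts = MutationSet(tuple(f"M{i}" for i in range(n)))
        paths = enumerate_paths(muts)
        assert len(paths) == math.factorial(n)
        assert all(len(p) == n + 1 for p in paths)

    def test_paths_are_monotone_single_additions(self):
        for path in enumerate_paths(THREE):
            for a, b in zip(path, path[1:]):
                assert b.order == a.order + 1
                assert set(a.mutations) < set(b.mutations)

    def test_four_mutation_paths_cover_full_hypercube(self):
        muts = MutationSet(("A", "B", "C", "D"))
        paths = enumerate_paths(muts)
        assert len(paths) == 24
        visited = {g.label for path in paths for g in path}
        assert visited == {g.label for g in enumerate_genotypes(muts)}

    def test_path_enumeration_guard(self):
        with pytest.raises(HypercubeSizeError):
            enumerate_paths(MutationSet(tuple(f"M{i}" for i in range(9))))

    def test_epistasis_pairs_for_three_mutations(self):
        pairs = epistasis_pairs(THREE)
        singles = [p for p in pairs if len(p[0]) == 1 and len(p[1]) == 1]
        mixed = [p for p in pairs if len(p[0]) + len(p[1]) == 3]
        assert len(singles) == 3 and len(mixed) == 3


class TestStepTest:
    def test_identical_samples_are_dashed(self, rng):
        values = rng.normal(size=10)
        a = PhenotypeSample("wt", values)
        b = PhenotypeSample("A", values + rng.normal(scale=1e-9, size=10))
        out = step_test(a, b)
        assert out.classification == "dashed"
        assert out.p_raw > 0.5

    def test_large_increase_is_solid(self, rng):
        a = PhenotypeSample("wt", rng.normal(0, 1, size=10))
        b = PhenotypeSample("A", a.values + 10)
        out = step_test(a, b)
        assert out.classification == "solid"
        assert out.direction == "increase"

    def test_significant_decrease_stays_dashed(self, rng):
        a = PhenotypeSample("wt", rng.normal(0, 1, size=10))
        b = PhenotypeSample("A", a.values - 10)
        out = step_test(a, b)
        assert out.p_corrected < 0.05
        assert out.direction == "decrease"
        assert out.classification == "dashed"

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValueError):
            step_test(PhenotypeSample("wt", [1.0, 2.0]), PhenotypeSample("A", [1.0, 2.0, 3.0]))


def additive_samples(rng, interaction=0.0, n=10, sd=5.0, mu0=10.0, a=20.0, b=20.0):
    initial = PhenotypeSample("wt", rng.normal(mu0, sd, n))
    int_a = PhenotypeSample("A", rng.normal(mu0 + a, sd, n))
    int_b = PhenotypeSample("B", rng.normal(mu0 + b, sd, n))
    combined = PhenotypeSample("A,B", rng.normal(mu0 + a + b + interaction, sd, n))
    return initial, int_a, int_b, combined


class TestEpistasisTest:
    def test_reproducible_for_same_seed(self, rng):
        samples = additive_samples(rng)
        r1 = epistasis_test(*samples, seed=42)
        r2 = epistasis_test(*samples, seed=42)
        assert np.array_equal(r1.expected_distribution, r2.expected_distribution)
        assert r1.p_raw == r2.p_raw

    def test_expected_distribution_length_is_n_boot(self, rng):
        result = epistasis_test(*additive_samples(rng), n_boot=250, seed=0)
        assert len(result.expected_distribution) == 250

    def test_strong_negative_interaction_detected(self, rng):
        """Combined genotype equal to the initial while both effects are +20:
        strong negative epistasis."""
        hits = 0
        for _ in range(50):
            initial, int_a, int_b, _ = additive_samples(rng)
            combined = PhenotypeSample("A,B", rng.normal(10.0, 5.0, 10))
            result = epistasis_test(initial, int_a, int_b, combined, seed=rng)
            hits += result.epistatic and result.sign == "negative"
        assert hits >= 45

    def test_all_null_identical_groups_not_flagged(self):
        """When both intermediates and the combination are literally the
        initial sample, the additive expectation matches and no epistasis
        is called."""
        values = np.array([8.0, 9.5, 10.0, 10.5, 11.0, 9.0, 10.2, 9.8, 10.8, 9.2])
        sample = lambda name: PhenotypeSample(name, values.copy())
        result = epistasis_test(sample("wt"), sample("A"), sample("B"), sample("A,B"), seed=7)
        assert not result.epistatic

    def test_exchangeability_of_intermediates(self, rng):
        """Swapping the two intermediate genotypes leaves the expected-sum
        law unchanged: distribution means agree across many seeds."""
        initial, int_a, int_b, combined = additive_samples(rng)
        means_ab, means_ba = [], []
        for seed in range(200):
            means_ab.append(epistasis_test(initial, int_a, int_b, combined, seed=seed).expected_mean)
            means_ba.append(epistasis_test(initial, int_b, int_a, combined, seed=seed).expected_mean)
        assert np.mean(means_ab) == pytest.approx(np.mean(means_ba), abs=0.5)

    def test_empty_sample_rejected(self, rng):
        initial, int_a, int_b, _ = additive_samples(rng)
        with pytest.raises(ValueError, match="empty"):
            epistasis_test(initial, int_a, int_b, PhenotypeSample("A,B", []), seed=0)

    def test_bonferroni_family_applied(self, rng):
        samples = additive_samples(rng, interaction=-30.0)
        r1 = epistasis_test(*samples, seed=3, m=1)
        r6 = epistasis_test(*samples, seed=3, m=6)
        assert r6.p_corrected == pytest.approx(min(1.0, 6 * r1.p_raw))


class TestRunLandscape:
    def test_additive_panel_recovers_programmed_effects(self):
        """mean(single) - mean(wt) on the C4 readout matches the programmed
        per-mutation effect within 2 SEM (parameter recovery)."""
        cfg, muts = ir75a_like_config(n_sensilla=50, seed=11)
        matrix, truth = simulate_panel(cfg, muts)
        report = run_landscape(matrix, muts, seed=1, phenotype="odor:C4")
        wt = report.phenotypes["wt"]
        for mutation, programmed in [("T289S", 15.0), ("Q536K", 20.0), ("F538L", 25.0)]:
            sample = report.phenotypes[mutation]
            est = sample.mean - wt.mean
            sem2 = 2 * np.hypot(sample.sem, wt.sem)
            assert abs(est - programmed) <= sem2 + 1e-9

    def test_programmed_negative_interaction_flagged(self):
        inter = {frozenset({"T289S", "Q536K"}): {"C4": -30.0}}
        cfg, muts = ir75a_like_config(seed=5, interaction=inter)
        matrix, _ = simulate_panel(cfg, muts)
        report = run_landscape(matrix, muts, seed=5, phenotype="odor:C4")
        flagged = {frozenset(p) for p in report.epistatic_pairs()}
        assert frozenset({"T289S", "Q536K"}) in flagged
        target = [r for r in report.epistasis if set(r.pair) == {"T289S", "Q536K"}][0]
        assert target.sign == "negative"

    def test_increasing_path_steps_solid_on_linear_phenotype(self):
        cfg, muts = ir75a_like_config(n_sensilla=25, noise_sd=3.0, seed=21)
        matrix, _ = simulate_panel(cfg, muts)
        report = run_landscape(matrix, muts, seed=2, phenotype="odor:C4")
        # every mutation raises C4 strongly, so all 12 edges should be solid
        assert all(s.classification == "solid" for s in report.steps)

    def test_missing_genotype_errors_with_labels(self):
        cfg, muts = ir75a_like_config(seed=3)
        matrix, _ = simulate_panel(cfg, muts)
        keep = matrix.labels != "T289S"
        from irtuning.tables_io import ResponseMatrix

        trimmed = ResponseMatrix(
            matrix.data.loc[keep], matrix.labels.loc[keep], matrix.sensilla.loc[keep]
        )
        with pytest.raises(MissingGenotypeError, match="T289S"):
            run_landscape(trimmed, muts, seed=0)

    def test_family_size_defaults_to_all_comparisons(self):
        cfg, muts = ir75a_like_config(seed=7)
        matrix, _ = simulate_panel(cfg, muts)
        report = run_landscape(matrix, muts, seed=7, phenotype="odor:C4")
        assert report.family_size == len(report.steps) + len(report.epistasis) == 12 + 6

    def test_report_files_written(self, tmp_path):
        cfg, muts = ir75a_like_config(seed=9)
        matrix, _ = simulate_panel(cfg, muts)
        report = run_landscape(matrix, muts, seed=9)
        paths = report.to_files(tmp_path)
        for p in paths.values():
            assert p.exists()
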