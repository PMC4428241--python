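"""Core/accessory classification, rarefaction, and model fitting."""

import math

import numpy as np
import pandas as pd
import pytest

import strainpan as sp
from strainpan.datatypes import PresenceMatrix
from strainpan.pangenome import (
    RarefactionTable,
    classify_genes,
    estimate_accessory_percent,
    fit_accessory_model,
    model_deviation,
    subsample_fractions,
)


def matrix_from_rows(rows, individuals=None):
    rows = np.asarray(rows, dtype=bool)
    individuals = individuals or [f"i{j}" for j in range(rows.shape[1])]
    df = pd.DataFrame(rows, columns=individuals,
                      index=[f"g{i}" for i in range(rows.shape[0])])
    return PresenceMatrix(species_id="spT", presence=df)


def table_from_curve(ks, values):
    df = pd.DataFrame(
        {
            "k": ks,
            "n_combinations": 1,
            "mean_fraction": values,
            "median_fraction": values,
            "fractions": [np.array([v]) for v in values],
        }
    )
    return RarefactionTable(species_id="spT", table=df, universe_size=100, exhaustive=False)


class TestClassifyGenes:
    def test_labels(self):
        m = matrix_from_rows(
            [[1] * 10, [0] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]]
        )
        res = classify_genes(m)
        assert list(res.labels) == ["core", "unobserved", "accessory"]
        assert res.counts == {"core": 1, "accessory": 1, "unobserved": 1}

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = rng.random((50, 8)) < 0.7
        m = matrix_from_rows(rows)
        perm = list(np.random.default_rng(1).permutation(m.individuals))
        m_perm = PresenceMatrix(species_id="spT", presence=m.presence[perm])
        assert (classify_genes(m).labels == classify_genes(m_perm).labels).all()

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError, match="2 individuals"):
            classify_genes(matrix_from_rows([[1]]))


class TestSubsampleFractions:
    def test_identical_individuals_zero_everywhere(self):
        m = matrix_from_rows(np.ones((20, 6)))
        t = subsample_fractions(m)
        assert (t.means() == 0.0).all()

    def test_three_individual_enumeration(self):
        # g0 in all, g1 only in individual 0; fixed universe = {g0, g1}
        m = matrix_from_rows([[1, 1, 1], [1, 0, 0]])
        t = subsample_fractions(m, sizes=[2])
        row = t.table.iloc[0]
        assert row["n_combinations"] == 3
        assert list(row["fractions"]) == [0.5, 0.5, 0.5]
        assert row["mean_fraction"] == 0.5

    def test_exhaustive_combination_count(self):
        m = matrix_from_rows(np.random.default_rng(3).random((30, 10)) < 0.8)
        t = subsample_fractions(m, sizes=[2])
        assert t.table.iloc[0]["n_combinations"] == math.comb(10, 2)

    def test_capped_combinations_distinct_and_seeded(self):
        m = matrix_from_rows(np.random.default_rng(4).random((30, 12)) < 0.8)
        t1 = subsample_fractions(m, sizes=[5], max_combinations=50, seed=9)
        t2 = subsample_fractions(m, sizes=[5], max_combinations=50, seed=9)
        assert t1.table.iloc[0]["n_combinations"] == 50
        assert list(t1.table.iloc[0]["fractions"]) == list(t2.table.iloc[0]["fractions"])

    def test_k_equals_n_recovers_accessory_fraction(self):
        rng = np.random.default_rng(5)
        m = matrix_from_rows(rng.random((200, 8)) < 0.85)
        t = subsample_fractions(m, sizes=[8])
        labels = classify_genes(m)
        expected = labels.counts["accessory"] / (
            labels.counts["accessory"] + labels.counts["core"]
        )
        assert t.means()[0] == pytest.approx(expected)

    def test_mean_non_decreasing_exhaustive(self):
        rng = np.random.default_rng(6)
        m = matrix_from_rows(rng.random((300, 9)) < 0.8)
        t = subsample_fractions(m)
        assert (np.diff(t.means()) >= -1e-12).all()

    def test_permutation_invariance_of_exhaustive_means(self):
        rng = np.random.default_rng(7)
        m = matrix_from_rows(rng.random((100, 6)) < 0.8)
        perm = list(np.random.default_rng(8).permutation(m.individuals))
        m_perm = PresenceMatrix(species_id="spT", presence=m.presence[perm])
        np.testing.assert_allclose(
            subsample_fractions(m).means(), subsample_fractions(m_perm).means()
        )

    def test_oversized_k_raises(self):
        m = matrix_from_rows(np.ones((5, 4)))
        with pytest.raises(ValueError, match="subset sizes"):
            subsample_fractions(m, sizes=[5])


class TestModelFitting:
    def test_exponential_self_fit_recovers_asymptote(self):
        ks = np.arange(2, 11)
        y = 0.30 - 0.30 * np.exp(-ks / 2.0)
        fit = fit_accessory_model(table_from_curve(ks, y), "exponential")
        assert fit.asymptote == pytest.approx(0.30, abs=1e-3)
        assert fit.parameters["b"] == pytest.approx(0.30, abs=1e-2)
        assert fit.parameters["c"] == pytest.approx(2.0, abs=0.05)

    def test_constant_curve_degenerate_asymptote(self):
        ks = np.arange(2, 11)
        fit = fit_accessory_model(table_from_curve(ks, np.full(9, 0.25)), "exponential")
        assert fit.asymptote == pytest.approx(0.25, abs=1e-6)

    def test_concave_increasing_asymptote_at_least_last_mean(self):
        ks = np.arange(2, 11)
        y = 0.4 * (1 - np.exp(-0.4 * ks))
        fit = fit_accessory_model(table_from_curve(ks, y), "exponential")
        assert fit.asymptote >= y[-1] - 1e-6

    def test_negative_exponential_self_fit(self):
        ks = np.arange(2, 11)
        y = 0.35 * (1 - np.exp(-0.5 * ks))
        fit = fit_accessory_model(table_from_curve(ks, y), "negative_exponential")
        assert fit.asymptote == pytest.approx(0.35, abs=1e-3)

    def test_power_law_flags_no_asymptote(self):
        ks = np.arange(2, 11)
        y = 0.1 * ks**0.3
        fit = fit_accessory_model(table_from_curve(ks, y), "power_law")
        assert fit.asymptote is None
        assert any("asymptote" in w for w in fit.warnings)

    def test_spline_passes_through_means(self):
        ks = np.arange(2, 11)
        y = 0.30 - 0.30 * np.exp(-ks / 2.0)
        fit = fit_accessory_model(table_from_curve(ks, y), "spline")
        np.testing.assert_allclose(fit.predict(ks), y, atol=1e-12)
        assert fit.asymptote is None

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            fit_accessory_model(table_from_curve([2, 3, 4], [0.1, 0.2, 0.25]), "heaps")


class TestEstimateAndDeviation:
    def test_percent_conversion(self):
        ks = np.arange(2, 11)
        y = 0.3228 - 0.25 * np.exp(-ks / 2.0)
        fit = fit_accessory_model(table_from_curve(ks, y), "exponential")
        assert estimate_accessory_percent(fit) == pytest.approx(32.28, abs=0.05)

    def test_zero_asymptote(self):
        ks = np.arange(2, 11)
        fit = fit_accessory_model(table_from_curve(ks, np.zeros(9)), "exponential")
        assert estimate_accessory_percent(fit) == pytest.approx(0.0, abs=1e-6)

    def test_spline_estimate_raises(self):
        fit = fit_accessory_model(table_from_curve([2, 3, 4], [0.1, 0.2, 0.25]), "spline")
        with pytest.raises(ValueError, match="horizon"):
            estimate_accessory_percent(fit)

    def test_exact_model_zero_deviation(self):
        ks = np.arange(2, 11)
        y = 0.30 - 0.30 * np.exp(-ks / 2.0)
        fit = fit_accessory_model(table_from_curve(ks, y), "exponential")
        far_ks = np.arange(2, 31)
        far_y = 0.30 - 0.30 * np.exp(-far_ks / 2.0)
        assert model_deviation(fit, table_from_curve(far_ks, far_y)) == pytest.approx(
            0.0, abs=0.05
        )

    def test_constant_offset_is_linear_in_pp(self):
        ks = np.arange(2, 11)
        y = 0.30 - 0.30 * np.exp(-ks / 2.0)
        fit = fit_accessory_model(table_from_curve(ks, y), "exponential")
        shifted = table_from_curve(ks, y + 0.05)
        assert model_deviation(fit, shifted) == pytest.approx(5.0, abs=0.1)

    def test_exponential_beats_power_law_on_saturating_truth(self):
        ks = np.arange(2, 11)
        truth = lambda k: 0.35 - 0.30 * np.exp(-k / 3.0)
        fit_e = fit_accessory_model(table_from_curve(ks, truth(ks)), "exponential")
        fit_p = fit_accessory_model(table_from_curve(ks, truth(ks)), "power_law")
        far = np.arange(11, 31)
        expected = table_from_curve(far, truth(far))
        assert model_deviation(fit_e, expected) < model_deviation(fit_p, expected)


class TestParameterRecovery:
    def test_asymptote_matches_supercohort_truth(self):
        """Exponential asymptote from a 10-individual cohort lands within 5pp
        of the brute-force accessory fraction of a 30-individual super-cohort."""
        for target, seed in [(0.2, 0), (0.32, 1), (0.45, 2)]:
            cfg = sp.SimulationConfig(
                n_genes=1000, n_contigs=2, n_individuals_per_species=30,
                true_accessory_fraction=target, presence_noise=0,
                biological_noise=0, technical_noise=0, seed=seed,
            )
            ref = sp.generate_reference(cfg)
            truth = sp.generate_strain_population(ref, cfg)
            cohort = truth.individuals[:10]
            mat = PresenceMatrix(species_id="s", presence=truth.true_presence[cohort])
            universe = mat.presence.any(axis=1)
            brute = float(
                (universe & (~truth.true_presence).any(axis=1)).sum() / universe.sum()
            )
            fit = fit_accessory_model(subsample_fractions(mat))
            assert abs(fit.asymptote - brute) * 100 <= 5.0
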