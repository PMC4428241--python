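"""Gene-content distances, rank-sum test, Fisher enrichment, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import strainpan as sp
from strainpan.compare import (
    abundance_independence_check,
    benjamini_hochberg,
    compare_distance_distributions,
    fisher_enrichment,
    pairwise_difference,
    reference_conditioned_difference,
    replicate_differences,
)
from strainpan.pangenome import GeneLabelVector


def vec(present, universe):
    return pd.Series([g in present for g in universe], index=list(universe))


class TestPairwiseDifference:
    UNIVERSE = ["g1", "g2", "g3", "g4", "g5"]

    def test_symmetric_difference_over_union(self):
        d = pairwise_difference(
            vec({"g1", "g2", "g3"}, self.UNIVERSE), vec({"g2", "g3", "g4"}, self.UNIVERSE)
        )
        assert d.n_symmetric_difference == 2 and d.n_union == 4
        assert d.value == 0.5

    def test_identity(self):
        a = vec({"g1", "g3"}, self.UNIVERSE)
        assert pairwise_difference(a, a.copy()).value == 0.0

    def test_disjoint_sets(self):
        d = pairwise_difference(
            vec({"g1", "g2"}, self.UNIVERSE), vec({"g3"}, self.UNIVERSE)
        )
        assert d.value == 1.0

    def test_empty_union_raises(self):
        with pytest.raises(ValueError, match="union"):
            pairwise_difference(vec(set(), self.UNIVERSE), vec(set(), self.UNIVERSE))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            pairwise_difference(np.array([True]), np.array([True, False]))

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()), min_size=1, max_size=40
        )
    )
    def test_metric_axioms_on_random_triples(self, rows):
        a = np.array([r[0] for r in rows])
        b = np.array([r[1] for r in rows])
        c = np.array([r[2] for r in rows])
        if not (a.any() and b.any() and c.any()):
            return
        dab = pairwise_difference(a, b).value
        dba = pairwise_difference(b, a).value
        dac = pairwise_difference(a, c).value
        dcb = pairwise_difference(c, b).value
        assert dab == dba
        assert (dab == 0) == bool((a == b).all())
        assert dab <= dac + dcb + 1e-12  # Jaccard distance triangle inequality


class TestReplicateDifferences:
    def _presence(self, samples, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return {
            s: pd.Series(rng.random(n) < 0.8, index=[f"g{i}" for i in range(n)])
            for s in samples
        }

    def test_pair_classification_counts(self):
        rows = []
        for i in range(10):
            rows.append((f"i{i}_t0_l1", f"i{i}", 0, 1))
        rows.append(("i0_t1_l1", "i0", 1, 1))  # biological pair for i0
        for lane in (2, 3, 4):
            rows.append((f"i1_t0_l{lane}", "i1", 0, lane))  # 4 lanes for i1
        rep = pd.DataFrame(rows, columns=["sample_id", "individual_id", "time_point", "lane"])
        diffs = replicate_differences(self._presence(rep["sample_id"]), rep)
        by_class = pd.Series([d.comparison_class for d in diffs]).value_counts()
        assert by_class["inter_individual"] == 45
        assert by_class["biological_replicate"] == 1
        assert by_class["technical_replicate"] == 6

    def test_empty_classes_allowed(self):
        rep = pd.DataFrame(
            [("a_t0", "a", 0, 1), ("b_t0", "b", 0, 1)],
            columns=["sample_id", "individual_id", "time_point", "lane"],
        )
        diffs = replicate_differences(self._presence(["a_t0", "b_t0"]), rep)
        assert len(diffs) == 1
        assert diffs[0].comparison_class == "inter_individual"


class TestReferenceConditioned:
    def test_worked_example(self):
        d = reference_conditioned_difference(
            {"g1", "g2", "g3"}, {"g1", "g2", "g4"}, {"g1", "g2", "g3", "g4", "g5"}
        )
        assert d.n_symmetric_difference == 2 and d.n_union == 4
        assert d.value == 0.5

    def test_identical_genomes(self):
        d = reference_conditioned_difference({"g1", "g2"}, {"g1", "g2"}, {"g1", "g2", "g3"})
        assert d.value == 0.0

    def test_non_reference_genes_ignored(self):
        base = reference_conditioned_difference({"g1"}, {"g2"}, {"g1", "g2"})
        with_extra = reference_conditioned_difference({"g1", "g6"}, {"g2"}, {"g1", "g2"})
        assert base.value == with_extra.value == 1.0

    def test_empty_denominator_raises(self):
        with pytest.raises(ValueError, match="reference"):
            reference_conditioned_difference({"g9"}, {"g8"}, {"g1"})

    def test_reduces_to_jaccard_when_reference_is_universe(self, rng):
        universe = [f"g{i}" for i in range(40)]
        a = {g for g in universe if rng.random() < 0.6}
        b = {g for g in universe if rng.random() < 0.6}
        cond = reference_conditioned_difference(a, b, set(universe))
        plain = pairwise_difference(vec(a, universe), vec(b, universe))
        assert cond.value == plain.value


class TestRankSum:
    def test_exact_small_sample(self):
        U, p = compare_distance_distributions([1, 2, 3], [10, 11, 12])
        assert U == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_enumeration_oracle(self):
        """Exact p equals brute-force enumeration over all labelings."""
        x, y = [1.0, 4.0, 5.0], [2.0, 3.0, 6.0]
        _, p = compare_distance_distributions(x, y)
        pooled = sorted(x + y)
        n = len(x)
        u_obs = sum(1 for xi in x for yi in y if xi > yi)
        us = []
        for combo in itertools.combinations(range(len(pooled)), n):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
            us.append(sum(1 for xi in xs for yi in ys if xi > yi))
        mean_u = n * n / 2
        extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
        assert p == pytest.approx(extreme / len(us), abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = compare_distance_distributions([1, 2, 3, 4], [1.5, 2.5, 3.5, 0.5])
        assert p > 0.6  # symmetric interleaving: far from significant

    def test_shifted_large_samples_significant(self, rng):
        x = rng.normal(1.0, 0.2, size=50)
        y = rng.normal(0.5, 0.2, size=50)
        _, p = compare_distance_distributions(x, y)
        assert p < 0.05

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_distance_distributions([], [1.0])


def brute_force_fisher(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration at fixed margins."""
    r1, c1, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (N - r1)), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, N, r1, c1)
    obs = pmf[a - lo]
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


def labels_from_counts(a_in, a_out, c_in, c_out):
    names, labs, cats = [], [], {}
    i = 0
    for count, lab, inc in [
        (a_in, "accessory", True),
        (a_out, "accessory", False),
        (c_in, "core", True),
        (c_out, "core", False),
    ]:
        for _ in range(count):
            g = f"g{i}"
            names.append(g)
            labs.append(lab)
            if inc:
                cats[g] = "cat1"
            i += 1
    lv = GeneLabelVector(
        species_id="spT",
        labels=pd.Series(labs, index=names),
        counts={"core": c_in + c_out, "accessory": a_in + a_out, "unobserved": 0},
    )
    return lv, pd.Series(cats)


class TestFisherEnrichment:
    def test_worked_example_p(self):
        lv, cats = labels_from_counts(8, 2, 2, 8)
        (res,) = fisher_enrichment(lv, cats)
        assert (res.n_accessory_in, res.n_accessory_out, res.n_core_in, res.n_core_out) == (
            8, 2, 2, 8,
        )
        assert res.p_value == pytest.approx(brute_force_fisher(8, 2, 2, 8), abs=1e-12)
        assert res.p_value == pytest.approx(0.023, abs=5e-4)

    def test_balanced_category_no_signal(self):
        lv, cats = labels_from_counts(5, 5, 5, 5)
        (res,) = fisher_enrichment(lv, cats)
        assert res.odds_ratio == 1.0 and res.p_value == 1.0

    def test_single_category_q_equals_p(self):
        lv, cats = labels_from_counts(6, 4, 2, 8)
        (res,) = fisher_enrichment(lv, cats)
        assert res.q_value == res.p_value

    def test_unobserved_genes_excluded(self):
        lv, cats = labels_from_counts(4, 4, 4, 4)
        lv.labels.iloc[0] = "unobserved"
        (res,) = fisher_enrichment(lv, cats)
        assert res.n_accessory_in == 3

    def test_doubling_method_at_least_min_tail(self):
        lv, cats = labels_from_counts(8, 2, 2, 8)
        (res_d,) = fisher_enrichment(lv, cats, two_sided_method="doubling")
        p_less = stats.fisher_exact([[8, 2], [2, 8]], alternative="less")[1]
        p_greater = stats.fisher_exact([[8, 2], [2, 8]], alternative="greater")[1]
        assert res_d.p_value == pytest.approx(min(1.0, 2 * min(p_less, p_greater)))


class TestBenjaminiHochberg:
    def test_q_at_least_p_and_monotone_step_up(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_single_test_identity(self):
        assert benjamini_hochberg([0.042])[0] == pytest.approx(0.042)


class TestAbundanceIndependence:
    def test_constant_fraction_flagged_undefined(self):
        rep = abundance_independence_check([0.3, 0.3, 0.3], [10, 20, 30], [0.1, 0.2, 0.3])
        assert rep["coverage"]["r"] is None
        assert "undefined" in rep["coverage"]["note"]

    def test_perfect_linear_relation(self):
        rep = abundance_independence_check([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        assert abs(rep["coverage"]["r"]) == pytest.approx(1.0)

    def test_independent_draws_rarely_correlate(self):
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            rep = abundance_independence_check(g.random(20), g.random(20), g.random(20))
            if abs(rep["coverage"]["r"]) < 0.5 and abs(rep["abundance"]["r"]) < 0.5:
                hits += 1
        assert hits >= 95

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="3 samples"):
            abundance_independence_check([0.1, 0.2], [1, 2])
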