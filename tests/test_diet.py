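"""Diet profiles, Morisita overlap and the Shannon niche decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophicniche import diet
from trophicniche.datatypes import DietMatrix, DietProfile, ValidationError

from ._oracles import shannon_decomposition_oracle


def _dm(rows):
    return DietMatrix(
        pd.DataFrame(rows, columns=["individual_id", "group", "prey_taxon",
                                    "count", "mass"])
    )


class TestBodyIndices:
    def test_gsi_and_fullness_are_percentages(self):
        assert diet.gsi(4.5, 100.0) == pytest.approx(4.5)
        assert diet.gsi(0.0, 100.0) == 0.0
        assert diet.fullness_index(12.0, 100.0) == pytest.approx(12.0)

    def test_nonpositive_body_mass_rejected(self):
        with pytest.raises(ValidationError):
            diet.gsi(1.0, 0.0)


class TestDietProfiles:
    def test_percent_by_weight_single_individual(self):
        dm = _dm([("i1", "g", "a", 1, 9.0), ("i1", "g", "b", 1, 1.0)])
        profiles, mean, sd = diet.percent_by_weight(dm, "g")
        np.testing.assert_allclose(profiles[0].proportions, [0.9, 0.1])

    def test_percent_by_weight_mean_and_sd_across_individuals(self):
        dm = _dm([("i1", "g", "a", 1, 1.0), ("i2", "g", "b", 1, 1.0)])
        _, mean, sd = diet.percent_by_weight(dm, "g")
        np.testing.assert_allclose(mean.proportions, [0.5, 0.5])
        np.testing.assert_allclose(sd, [0.70710678, 0.70710678], atol=1e-6)

    def test_percent_by_number_excludes_detritus(self):
        dm = _dm([("i1", "g", "detritus", 900, 90.0),
                  ("i1", "g", "a", 50, 1.0), ("i1", "g", "b", 50, 1.0)])
        profiles, mean, _ = diet.percent_by_number(dm, "g")
        assert "detritus" not in mean.labels
        np.testing.assert_allclose(mean.proportions, [0.5, 0.5])

    def test_detritus_only_individual_dropped_with_warning(self):
        dm = _dm([("i1", "g", "detritus", 10, 5.0),
                  ("i2", "g", "a", 4, 1.0), ("i2", "g", "b", 6, 1.0)])
        with pytest.warns(UserWarning, match="i1"):
            profiles, _, _ = diet.percent_by_number(dm, "g")
        assert len(profiles) == 1

    def test_percent_by_number_is_count_over_total(self):
        counts = (536, 125, 117, 93, 44, 59, 10, 16)
        dm = _dm([("i1", "g", f"t{k}", c, 1.0) for k, c in enumerate(counts)])
        profiles, _, _ = diet.percent_by_number(dm, "g")
        np.testing.assert_allclose(
            profiles[0].proportions, np.array(counts) / 1000.0, atol=1e-12
        )


class TestMorisita:
    def test_identical_profiles_overlap_fully(self):
        p = DietProfile(labels=list("abc"), proportions=[0.5, 0.3, 0.2])
        assert diet.morisita_index(p, p) == pytest.approx(1.0)

    def test_disjoint_supports_do_not_overlap(self):
        p = DietProfile(labels=list("ab"), proportions=[1.0, 0.0])
        q = DietProfile(labels=list("ab"), proportions=[0.0, 1.0])
        assert diet.morisita_index(p, q) == 0.0

    def test_threshold_call_is_strict(self):
        assert diet.overlap_significant(0.61)
        assert not diet.overlap_significant(0.6)
        assert diet.overlap_significant(0.982)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=6),
        q=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=6),
    )
    def test_symmetric_bounded_and_order_invariant(self, p, q):
        k = min(len(p), len(q))
        labels = [f"t{i}" for i in range(k)]
        pp = DietProfile(labels=labels, proportions=p[:k])
        qq = DietProfile(labels=labels, proportions=q[:k])
        c = diet.morisita_index(pp, qq)
        assert 0.0 <= c <= 1.0 + 1e-12
        assert c == pytest.approx(diet.morisita_index(qq, pp))
        perm = list(reversed(range(k)))
        pr = DietProfile(labels=[labels[i] for i in perm],
                         proportions=pp.proportions[perm])
        qr = DietProfile(labels=[labels[i] for i in perm],
                         proportions=qq.proportions[perm])
        assert c == pytest.approx(diet.morisita_index(pr, qr))

    def test_profiles_align_on_union_vocabulary(self):
        p = DietProfile(labels=["a", "b"], proportions=[0.6, 0.4])
        q = DietProfile(labels=["b", "c"], proportions=[0.4, 0.6])
        c = diet.morisita_index(p, q)
        # overlap only through taxon b
        assert c == pytest.approx(2 * 0.4 * 0.4 / (0.52 + 0.52))


class TestNicheDecomposition:
    def test_identical_individuals_have_no_between_component(self):
        dm = _dm([(f"i{j}", "g", t, c, float(c))
                  for j in range(3) for t, c in zip("abc", (5, 3, 2))])
        res = diet.tnw_wic(dm, "g")
        assert res.wic_over_tnw == pytest.approx(1.0)
        assert res.bic == pytest.approx(0.0, abs=1e-12)

    def test_perfect_specialists(self, two_specialists):
        res = diet.tnw_wic(two_specialists, "g")
        assert res.tnw == pytest.approx(np.log(2))
        assert res.wic == pytest.approx(0.0, abs=1e-12)
        assert res.wic_over_tnw == pytest.approx(0.0, abs=1e-12)

    def test_three_way_specialists_reach_log3(self):
        dm = _dm([(f"i{k}", "g", f"t{k}", 10, 10.0) for k in range(3)])
        res = diet.tnw_wic(dm, "g")
        assert res.tnw == pytest.approx(np.log(3))
        assert res.wic_over_tnw == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_counts_8_2(self, counts_8_2):
        res = diet.tnw_wic(counts_8_2, "g")
        h_ind = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2))
        assert res.tnw == pytest.approx(np.log(2))
        assert res.wic == pytest.approx(h_ind)
        assert res.wic_over_tnw == pytest.approx(h_ind / np.log(2), abs=1e-9)

    def test_degenerate_single_resource_flagged(self):
        dm = _dm([("i1", "g", "a", 5, 5.0), ("i2", "g", "a", 7, 7.0)])
        res = diet.tnw_wic(dm, "g")
        assert res.degenerate
        assert res.wic_over_tnw == 1.0

    def test_decomposition_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n_ind = rng.integers(2, 8)
            k = rng.integers(2, 6)
            arr = rng.integers(0, 20, size=(n_ind, k)).astype(float)
            arr[arr.sum(axis=1) == 0, 0] = 1  # keep every row positive
            rows = [(f"i{i}", "g", f"t{j}", int(arr[i, j]), float(arr[i, j]))
                    for i in range(n_ind) for j in range(k) if arr[i, j] > 0]
            res = diet.tnw_wic(_dm(rows), "g")
            tnw, wic, bic = shannon_decomposition_oracle(arr)
            assert res.tnw == pytest.approx(tnw, abs=1e-9)
            assert res.wic == pytest.approx(wic, abs=1e-9)
            assert res.bic == pytest.approx(bic, abs=1e-9)
            assert res.tnw == pytest.approx(res.wic + res.bic, abs=1e-9)
            assert 0.0 - 1e-12 <= res.wic <= res.tnw + 1e-12


class TestDietSimilarity:
    def test_identical_individuals_fully_similar(self):
        dm = _dm([(f"i{j}", "g", t, c, float(c))
                  for j in range(2) for t, c in zip("ab", (6, 4))])
        assert diet.mean_diet_similarity(dm, "g") == pytest.approx(1.0)

    def test_disjoint_specialists_not_similar(self, two_specialists):
        assert diet.mean_diet_similarity(two_specialists, "g") == 0.0

    def test_three_individual_hand_example(self):
        dm = _dm([("i1", "g", "a", 10, 10.0),
                  ("i2", "g", "b", 10, 10.0),
                  ("i3", "g", "a", 5, 5.0), ("i3", "g", "b", 5, 5.0)])
        # pairwise PS: (i1,i2)=0, (i1,i3)=0.5, (i2,i3)=0.5
        assert diet.mean_diet_similarity(dm, "g") == pytest.approx(1 / 3)


class TestRichness:
    def test_single_gut(self):
        dm = _dm([("i1", "g", t, 1, 1.0) for t in "abc"])
        assert diet.taxonomic_richness(dm, "g") == (3.0, 0.0)

    def test_empty_gut_counts_zero(self):
        dm = _dm([("i1", "g", "a", 0, 1.0), ("i2", "g", "a", 4, 1.0)])
        mean, sd = diet.taxonomic_richness(dm, "g")
        assert mean == pytest.approx(0.5)


def test_specialization_and_similarity_rise_together():
    """More concentrated Dirichlet individuals -> higher WIC/TNW and higher
    pairwise similarity: the mechanism linking the two specialization axes."""
    from trophicniche import simulate

    ratios, sims = [], []
    for alpha in (0.1, 1.0, 10.0, 100.0):
        r_a, s_a = [], []
        for seed in range(10):
            cfg = simulate.DietSimConfig(
                group_sizes={"g": 20}, baseline={"g": np.full(4, 0.25)},
                taxa=list("abcd"), concentration=alpha, seed=seed,
            )
            dm = simulate.simulate_diet(cfg)
            r_a.append(diet.tnw_wic(dm, "g").wic_over_tnw)
            s_a.append(diet.mean_diet_similarity(dm, "g"))
        ratios.append(np.median(r_a))
        sims.append(np.median(s_a))
    assert ratios == sorted(ratios)
    assert sims == sorted(sims)
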