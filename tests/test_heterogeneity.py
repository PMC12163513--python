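from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphohet.heterogeneity import (
    H_MAX,
    cluster_tumor_profiles,
    dmc_pattern,
    dmc_string,
    dominance_ranking,
    group_median_profiles,
    nsi,
    nsi_class,
    shannon_index,
    tumor_summary,
)
from morphohet.types import Morphotype, ValidationError

from conftest import make_profile

M = Morphotype
UNIFORM = np.ones(6) / 6


class TestShannonNSI:
    def test_uniform_profile_attains_the_printed_maximum(self):
        h = shannon_index(UNIFORM)
        assert h == pytest.approx(np.log(6))
        assert round(h, 2) == 1.79
        assert nsi(UNIFORM) == pytest.approx(1.0)

    def test_single_morphotype_gives_zero(self):
        assert shannon_index([1, 0, 0, 0, 0, 0]) == 0.0
        assert nsi([1, 0, 0, 0, 0, 0]) == 0.0

    def test_two_equal_morphotypes_closed_form(self):
        assert shannon_index([0.5, 0.5, 0, 0, 0, 0]) == pytest.approx(np.log(2))
        assert nsi([0.5, 0.5, 0, 0, 0, 0]) == pytest.approx(np.log(2) / np.log(6))

    def test_non_normalized_input_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            shannon_index([0.5, 0.4, 0, 0, 0, 0])

    @settings(max_examples=50, deadline=None)
    @given(perm=st.permutations(list(range(6))), seed=st.integers(0, 10**6))
    def test_nsi_permutation_invariant(self, perm, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(6))
        assert nsi(p[np.array(perm)]) == pytest.approx(nsi(p))

    def test_uniform_is_the_unique_maximizer_over_random_simplex(self):
        rng = np.random.default_rng(1)
        samples = rng.dirichlet(np.ones(6), size=10_000)
        values = [nsi(p) for p in samples]
        assert max(values) <= nsi(UNIFORM)
        assert all(0 <= v <= 1 for v in values)


class TestDominance:
    def test_sorting_by_proportion(self):
        r = dominance_ranking(make_profile([0.5, 0, 0, 0.3, 0.2, 0]))
        assert r.ordered_morphotypes == [M.CT, M.PP, M.DE]
        assert (r.dominant, r.secondary, r.tertiary) == (M.CT, M.PP, M.DE)
        assert not r.tie_flag

    def test_exact_tie_breaks_by_canonical_order_and_flags(self):
        r = dominance_ranking(make_profile([0.4, 0.4, 0.2, 0, 0, 0]))
        assert r.ordered_morphotypes == [M.CT, M.TB, M.MU]
        assert r.tie_flag

    def test_pure_profile_has_single_entry(self):
        r = dominance_ranking(make_profile([1, 0, 0, 0, 0, 0]))
        assert r.ordered_morphotypes == [M.CT]
        assert r.secondary is None

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            dominance_ranking(make_profile([0, 0, 0, 0, 0, 0]))


class TestDMCPattern:
    @pytest.mark.parametrize(
        "dominants, multiset, pattern",
        [
            ([M.CT, M.CT, M.CT, M.PP], {M.CT: 3, M.PP: 1}, "3+1"),
            ([M.CT, M.CT, M.PP, M.PP], {M.CT: 2, M.PP: 2}, "2+2"),
            ([M.CT] * 4, {M.CT: 4}, "4"),
            ([M.CT, M.PP, M.DE, M.MU], {M.CT: 1, M.PP: 1, M.DE: 1, M.MU: 1}, "1+1+1+1"),
            ([M.DE, M.CT, M.CT, M.SE], {M.CT: 2, M.DE: 1, M.SE: 1}, "2+1+1"),
        ],
    )
    def test_pattern_examples(self, dominants, multiset, pattern):
        ms, pc = dmc_pattern(dominants)
        assert ms == Counter(multiset)
        assert pc == pattern

    def test_agrees_with_exhaustive_enumeration_of_all_quadruples(self):
        for quad in product(M, repeat=4):
            ms, pc = dmc_pattern(list(quad))
            counts = sorted((list(quad).count(m) for m in set(quad)), reverse=True)
            assert pc == "+".join(map(str, counts))
            assert sum(ms.values()) == 4

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            dmc_pattern([M.CT] * 3)

    def test_dmc_string_orders_by_count_then_canonical(self):
        ms, _ = dmc_pattern([M.PP, M.CT, M.CT, M.CT])
        assert dmc_string(ms) == "3xCT+1xPP"


class TestTumorSummary:
    def test_identical_sections_idempotent(self):
        p = [0.5, 0.2, 0.1, 0.1, 0.05, 0.05]
        profiles = [make_profile(p, section_id=f"S{i}") for i in range(4)]
        s = tumor_summary(profiles)
        np.testing.assert_allclose(s.mean_profile, p)
        assert s.tumor_nsi == pytest.approx(nsi(p))
        assert s.pattern_class == "4"

    def test_four_pure_sections_closed_form(self):
        profiles = [
            make_profile(np.eye(6)[i], section_id=f"S{i}") for i in range(4)
        ]
        s = tumor_summary(profiles)
        np.testing.assert_allclose(s.mean_profile, [0.25, 0.25, 0.25, 0.25, 0, 0])
        assert s.tumor_nsi == pytest.approx(np.log(4) / np.log(6))
        assert s.pattern_class == "1+1+1+1"
        assert s.n_distinct_dominants == 4

    def test_mean_matches_independent_arithmetic(self, rng):
        vecs = rng.dirichlet(np.ones(6), size=4)
        profiles = [make_profile(v, section_id=f"S{i}") for i, v in enumerate(vecs)]
        s = tumor_summary(profiles)
        np.testing.assert_allclose(s.mean_profile, vecs.sum(axis=0) / 4, atol=1e-12)

    def test_empty_sections_excluded_and_dmc_withheld_below_four(self):
        profiles = [make_profile([1, 0, 0, 0, 0, 0], section_id="S1"),
                    make_profile([0, 0, 0, 0, 0, 0], section_id="S2")]
        s = tumor_summary(profiles)
        assert s.n_valid_sections == 1
        assert s.dmc_multiset is None and s.pattern_class is None
        with pytest.raises(ValidationError):
            tumor_summary([make_profile([0, 0, 0, 0, 0, 0])])


class TestNSIClass:
    @pytest.mark.parametrize(
        "value, cls",
        [(0.2, "low"), (0.5, "medium"), (0.3, "medium"), (0.7, "medium"),
         (0.71, "high"), (0.0, "low"), (1.0, "high")],
    )
    def test_class_boundaries(self, value, cls):
        assert nsi_class(value) == cls

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            nsi_class(1.2)


class TestClustering:
    @staticmethod
    def _summaries(vectors):
        out = []
        for i, v in enumerate(vectors):
            profiles = [make_profile(v, section_id=f"T{i}S{j}", tumor_id=f"T{i}")
                        for j in range(4)]
            out.append(tumor_summary(profiles))
        return out

    def test_two_separated_groups_recovered(self, rng):
        a = np.array([0.9, 0.02, 0.02, 0.02, 0.02, 0.02])
        b = np.array([0.02, 0.02, 0.02, 0.02, 0.02, 0.9])
        vecs = [a + 0 for _ in range(10)] + [b + 0 for _ in range(10)]
        summaries = self._summaries(vecs)
        labels = cluster_tumor_profiles(summaries, k=2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_gives_singletons(self, rng):
        vecs = rng.dirichlet(np.ones(6), size=5)
        labels = cluster_tumor_profiles(self._summaries(vecs), k=5)
        assert sorted(labels) == [1, 2, 3, 4, 5]

    def test_duplicated_rows_share_cluster(self, rng):
        vecs = list(rng.dirichlet(np.ones(6), size=4))
        summaries = self._summaries(vecs + vecs)  # each profile duplicated
        labels = cluster_tumor_profiles(summaries, k=4)
        assert all(labels[i] == labels[i + 4] for i in range(4))

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValidationError):
            cluster_tumor_profiles(self._summaries(rng.dirichlet(np.ones(6), size=3)), k=4)

    def test_group_median_mode_keys_by_dmc(self):
        a = np.array([0.9, 0.02, 0.02, 0.02, 0.02, 0.02])
        med = group_median_profiles(self._summaries([a, a]))
        assert list(med) == ["4xCT"]
        np.testing.assert_allclose(med["4xCT"], a)
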