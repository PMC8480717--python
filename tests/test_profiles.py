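"""Cross-sample matrices, class overlap, species tallies and t-tests."""

import itertools

import numpy as np
import pytest

from xenomir.classify import MiRNAGroup, parse_mirbase_id
from xenomir.profiles import (
    build_matrix,
    class_abundance_tests,
    presence_overlap,
    species_source_counts,
    ttest_unpaired,
)
from xenomir.quantify import AbundanceRecord, SampleProfile, log_transform, rpm

from _oracles import pooled_ttest


def _profile(sample_id, cells, total=1_000_000):
    records = [
        AbundanceRecord(gid, int(v), float(v), log_transform(float(v)))
        for gid, v in cells.items()
    ]
    return SampleProfile(sample_id, total, records)


class TestBuildMatrix:
    def test_union_of_groups_with_zero_fill(self):
        m = build_matrix(
            [_profile("s1", {"miR166_2": 5.0}), _profile("s2", {"miR156_1": 2.0})],
            {"s1": "blood", "s2": "saliva"},
        )
        assert m.group_ids == ["miR156_1", "miR166_2"]
        assert m.data.loc["s1", "miR156_1"] == 0.0
        assert m.data.loc["s2", "miR156_1"] == 2.0

    def test_single_profile_matches_itself(self):
        m = build_matrix([_profile("s1", {"g": 7.0})], {"s1": "blood"})
        assert m.data.shape == (1, 1) and m.data.loc["s1", "g"] == 7.0

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(ValueError):
            build_matrix(
                [_profile("s1", {"g": 1.0}), _profile("s1", {"g": 2.0})],
                {"s1": "blood"},
            )

    def test_row_sums_equal_profile_sums(self, rng):
        profiles = []
        for i in range(8):
            cells = {
                f"g{j}": float(rng.integers(0, 50))
                for j in rng.choice(20, size=6, replace=False)
            }
            profiles.append(_profile(f"s{i}", cells))
        m = build_matrix(profiles, {f"s{i}": "c" for i in range(8)})
        for p in profiles:
            assert m.data.loc[p.sample_id].sum() == pytest.approx(
                sum(r.rpm for r in p.records)
            )

    def test_input_order_invariance(self):
        profiles = [_profile("s1", {"a": 1.0}), _profile("s2", {"b": 2.0})]
        classes = {"s1": "x", "s2": "y"}
        fwd = build_matrix(profiles, classes)
        rev = build_matrix(profiles[::-1], classes)
        assert fwd.data.equals(rev.data)


class TestPresenceOverlap:
    def test_single_class_counts_present_groups(self):
        m = build_matrix(
            [_profile("s1", {"a": 1.0, "b": 0.0})], {"s1": "blood"}
        )
        regions, unique = presence_overlap(m)
        assert regions[("blood",)] == 1  # rpm > 0 only for "a"
        assert unique["blood"] == 1.0

    def test_disjoint_classes_no_intersection(self):
        m = build_matrix(
            [_profile("s1", {"a": 1.0}), _profile("s2", {"b": 1.0})],
            {"s1": "blood", "s2": "urine"},
        )
        regions, _ = presence_overlap(m)
        assert regions[("blood", "urine")] == 0
        assert regions[("blood",)] == 1 and regions[("urine",)] == 1

    def test_four_classes_match_power_set_oracle(self, rng):
        classes = ["blood", "milk", "saliva", "urine"]
        groups = [f"g{i}" for i in range(30)]
        # plant a random presence pattern: class -> set of groups
        membership = {
            g: {c for c in classes if rng.random() < 0.5} for g in groups
        }
        profiles = []
        for idx, c in enumerate(classes):
            cells = {g: 5.0 for g, cls in membership.items() if c in cls}
            profiles.append(_profile(f"s{idx}", cells))
        m = build_matrix(profiles, {f"s{idx}": c for idx, c in enumerate(classes)})
        regions, _ = presence_overlap(m)
        # brute-force oracle over the power set
        for k in range(1, 5):
            for subset in itertools.combinations(classes, k):
                expected = sum(
                    1 for g in groups if membership[g] == set(subset)
                )
                assert regions[subset] == expected
        total_present = sum(1 for g in groups if membership[g])
        assert sum(regions.values()) == total_present


class TestSpeciesSourceCounts:
    def _group(self, family, species, n=1):
        return MiRNAGroup(
            group_id=f"{family}_{n}",
            family=family,
            member_ids=[parse_mirbase_id(f"{s}-{family}a") for s in sorted(species)],
            sequence="ACGT",
            species=set(species),
        )

    def test_shared_sequence_credits_both_species(self):
        counts = species_source_counts([self._group("miR166", {"osa", "ath"})])
        assert counts == {"ath": 1, "osa": 1}

    def test_same_family_twice_counts_once(self):
        groups = [
            self._group("miR166", {"osa"}),
            self._group("miR166", {"osa"}, n=2),
        ]
        assert species_source_counts(groups) == {"osa": 1}

    def test_random_attribution_matches_nested_loop_oracle(self, rng):
        species_pool = ["osa", "ath", "zma", "gma"]
        fams = [f"miR{100 + i}" for i in range(12)]
        groups = []
        for fam in fams:
            for rep in range(int(rng.integers(1, 3))):
                chosen = {
                    s for s in species_pool if rng.random() < 0.5
                } or {"osa"}
                groups.append(self._group(fam, chosen, n=rep + 1))
        got = species_source_counts(groups)
        expected = {}
        for s in species_pool:
            n = len({g.family for g in groups if s in g.species})
            if n:
                expected[s] = n
        assert got == expected


class TestTTest:
    def test_identical_samples_give_p_one(self):
        res = ttest_unpaired([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0
        assert not res.significant

    def test_matches_closed_form_on_seeded_normal_draws(self, rng):
        """Seeded N(0,1) vs N(2,1) draws, n=10 each, 50 repetitions: t and p
        equal the textbook pooled-SD arithmetic to 1e-9."""
        for _ in range(50):
            x = list(rng.normal(0, 1, size=10))
            y = list(rng.normal(2, 1, size=10))
            res = ttest_unpaired(x, y)
            t, df, p = pooled_ttest(x, y)
            assert res.t_statistic == pytest.approx(t, abs=1e-9)
            assert res.degrees_of_freedom == df == 18
            assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_symmetry_negates_t_keeps_p(self, rng):
        x = list(rng.normal(0, 1, size=8))
        y = list(rng.normal(1, 2, size=12))
        a, b = ttest_unpaired(x, y), ttest_unpaired(y, x)
        assert a.t_statistic == pytest.approx(-b.t_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_zero_variance_unequal_means(self):
        res = ttest_unpaired([1.0, 1.0], [2.0, 2.0])
        assert res.p_value == 0.0 and res.degenerate and res.significant

    def test_welch_differs_under_unequal_variance(self, rng):
        x = list(rng.normal(0, 1, size=6))
        y = list(rng.normal(1, 5, size=20))
        student = ttest_unpaired(x, y)
        welch = ttest_unpaired(x, y, welch=True)
        assert welch.degrees_of_freedom != student.degrees_of_freedom

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ttest_unpaired([1.0], [1.0, 2.0])


class TestClassAbundanceTests:
    def test_pairwise_comparisons_emitted(self, rng):
        profiles = []
        classes = {}
        for i in range(4):
            profiles.append(_profile(f"b{i}", {"g": float(rng.integers(1, 10))}))
            classes[f"b{i}"] = "blood"
        for i in range(4):
            profiles.append(_profile(f"u{i}", {"g": float(rng.integers(50, 90))}))
            classes[f"u{i}"] = "urine"
        m = build_matrix(profiles, classes)
        stats = class_abundance_tests(m)
        assert list(stats["comparison"]) == ["blood_vs_urine"]
        assert 0.0 <= stats.loc[0, "p"] <= 1.0
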