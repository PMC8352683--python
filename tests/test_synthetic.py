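"""Generator structure, noise statistics, and the worked-example fixture."""

import dataclasses

import numpy as np
import pytest

from symdx.cascade import CascadeConfig, ConcurrenceClass
from symdx.errors import ConfigError
from symdx.evaluation import loocv
from symdx.synthetic import (
    GeneratorConfig,
    disjoint_config,
    generate_concurrence_records,
    generate_records,
    generate_taxonomy,
    reference_config,
)


class TestGenerateTaxonomy:
    def test_cube_taxonomy_counts(self):
        cfg = disjoint_config(seed=0)
        tax, prof = generate_taxonomy(cfg)
        assert len(tax.codes_at("main")) == 3
        assert len(tax.codes_at("subclass")) == 9
        assert len(tax.codes_at("disease")) == 27
        assert len(tax.all_codes()) == 39
        assert set(prof.profiles) == set(tax.codes_at("disease"))

    def test_zero_overlap_makes_sibling_profiles_disjoint(self):
        cfg = GeneratorConfig(B=2, t_b_range=(2, 2), t_bj_range=(3, 3),
                              n_symptoms=40, profile_size_range=(3, 4),
                              within_subclass_overlap=0.0, flip_noise=0.0,
                              gender_bias=(0.5, 0.5), n_per_disease=1, seed=3)
        tax, prof = generate_taxonomy(cfg)
        for sub in tax.codes_at("subclass"):
            leaves = tax.children_of(sub)
            for i, a in enumerate(leaves):
                for b in leaves[i + 1:]:
                    assert not (prof.profiles[a] & prof.profiles[b])

    def test_positive_overlap_makes_siblings_share_symptoms(self):
        cfg = reference_config(seed=4)
        tax, prof = generate_taxonomy(cfg)
        shares = []
        for sub in tax.codes_at("subclass"):
            leaves = tax.children_of(sub)
            for i, a in enumerate(leaves):
                for b in leaves[i + 1:]:
                    pa, pb = prof.profiles[a], prof.profiles[b]
                    shares.append(len(pa & pb) / min(len(pa), len(pb)))
        assert np.mean(shares) > 0.2

    def test_seeded_determinism(self):
        for maker in (lambda: generate_taxonomy(reference_config(seed=6)),):
            (tax_a, prof_a), (tax_b, prof_b) = maker(), maker()
            assert tax_a == tax_b
            assert prof_a.profiles == prof_b.profiles
            assert prof_a.gender_prevalence == prof_b.gender_prevalence

    def test_infeasible_pool_rejected(self):
        with pytest.raises(ConfigError):
            generate_taxonomy(GeneratorConfig(
                B=3, t_b_range=(3, 3), t_bj_range=(3, 3), n_symptoms=10,
                profile_size_range=(2, 2), within_subclass_overlap=0.0,
                flip_noise=0.0, gender_bias=(0.5, 0.5), n_per_disease=1,
                seed=0, global_disjoint=True))

    @pytest.mark.parametrize(
        "bad",
        [
            dict(flip_noise=1.5),
            dict(within_subclass_overlap=-0.1),
            dict(profile_size_range=(5, 3)),
            dict(t_bj_range=(2, 10)),
            dict(n_symptoms=4, profile_size_range=(4, 7)),
            dict(global_disjoint=True, within_subclass_overlap=0.4),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            GeneratorConfig(**bad)


class TestGenerateRecords:
    def test_zero_noise_records_repeat_their_profile(self):
        cfg = dataclasses.replace(disjoint_config(seed=2, n_per_disease=4),
                                  gender_bias=(1.0, 1.0))
        tax, prof = generate_taxonomy(cfg)
        records = generate_records(tax, prof, cfg)
        by_code = {}
        for r in records:
            by_code.setdefault(r.disease_code, set()).add(r.symptoms)
        assert all(len(v) == 1 for v in by_code.values())

    def test_profiles_recoverable_from_clean_records(self):
        cfg = disjoint_config(seed=12, n_per_disease=2)
        tax, prof = generate_taxonomy(cfg)
        for r in generate_records(tax, prof, cfg):
            on = frozenset(i for i, v in enumerate(r.symptoms) if v and i != 0)
            assert on == prof.profiles[r.disease_code]

    def test_flip_noise_hamming_distance_matches_binomial(self):
        cfg = dataclasses.replace(disjoint_config(seed=5, n_per_disease=40),
                                  flip_noise=0.5, global_disjoint=True,
                                  within_subclass_overlap=0.0)
        tax, prof = generate_taxonomy(cfg)
        records = generate_records(tax, prof, cfg)
        m = tax.n_symptoms - 1  # gender is never flipped
        dists = []
        for r in records:
            profile_flags = np.zeros(tax.n_symptoms, dtype=int)
            profile_flags[list(prof.profiles[r.disease_code])] = 1
            dists.append(np.sum(np.array(r.symptoms[1:]) != profile_flags[1:]))
        mean, sd = m * 0.5, np.sqrt(m * 0.25)
        assert abs(np.mean(dists) - mean) <= 3 * sd / np.sqrt(len(dists))

    def test_expected_flag_count_closed_form(self):
        p = 0.08
        cfg = reference_config(seed=7, n_per_disease=60)
        tax, prof = generate_taxonomy(cfg)
        records = generate_records(tax, prof, cfg)
        m = tax.n_symptoms - 1
        resid = []
        for r in records:
            k = len(prof.profiles[r.disease_code])
            expected = k * (1 - p) + (m - k) * p
            resid.append(sum(r.symptoms[1:]) - expected)
        # mean residual ~ N(0, sigma/sqrt(n)); sigma < sqrt(m)
        assert abs(np.mean(resid)) <= 3 * np.sqrt(m) / np.sqrt(len(resid))

    def test_records_deterministic_per_seed(self):
        cfg = reference_config(seed=9, n_per_disease=2)
        tax, prof = generate_taxonomy(cfg)
        assert generate_records(tax, prof, cfg) == generate_records(tax, prof, cfg)


class TestConcurrenceRecords:
    def test_disjoint_pair_flag_count_is_sum_of_profiles(self):
        cfg = dataclasses.replace(disjoint_config(seed=3, n_per_disease=2),
                                  gender_bias=(0.0, 0.0))
        tax, prof = generate_taxonomy(cfg)
        subs = tax.codes_at("subclass")
        combos = [ConcurrenceClass(frozenset(subs[:2])),
                  ConcurrenceClass(frozenset(subs[1:3]))]
        for flags, combo in generate_concurrence_records(tax, prof, combos,
                                                         cfg, n_per_combo=6):
            # profiles are globally disjoint and 2 symptoms each
            assert sum(flags) == 4
            assert flags[0] == 0

    def test_triple_combos_labelled_from_declared_sets_only(self):
        cfg = disjoint_config(seed=6)
        tax, prof = generate_taxonomy(cfg)
        subs = tax.codes_at("subclass")
        combos = [ConcurrenceClass(frozenset(subs[:3])),
                  ConcurrenceClass(frozenset(subs[3:6]))]
        records = generate_concurrence_records(tax, prof, combos, cfg,
                                               n_per_combo=4)
        assert {c.key for _, c in records} == {c.key for c in combos}
        assert all(len(c.member_codes) == 3 for _, c in records)

    def test_identical_symptom_cover_warns_at_zero_noise(self):
        from symdx.synthetic import SymptomProfiles

        cfg = disjoint_config(seed=1)
        tax, prof = generate_taxonomy(cfg)
        subs = tax.codes_at("subclass")
        # craft profiles so two different subclasses cover the same symptoms
        clone = dict(prof.profiles)
        for a_leaf, b_leaf in zip(tax.children_of(subs[1]),
                                  tax.children_of(subs[2])):
            clone[b_leaf] = clone[a_leaf]
        rigged = SymptomProfiles(profiles=clone,
                                 gender_prevalence=prof.gender_prevalence)
        combos = [ConcurrenceClass(frozenset([subs[0], subs[1]])),
                  ConcurrenceClass(frozenset([subs[0], subs[2]]))]
        with pytest.warns(UserWarning):
            generate_concurrence_records(tax, rigged, combos, cfg,
                                         n_per_combo=1)

    def test_non_subclass_member_rejected(self):
        cfg = disjoint_config(seed=1)
        tax, prof = generate_taxonomy(cfg)
        leafy = ConcurrenceClass(frozenset(tax.codes_at("disease")[:2]))
        with pytest.raises(ConfigError):
            generate_concurrence_records(tax, prof, [leafy], cfg)


class TestDifficultyMonotoneInNoise:
    def test_loocv_accuracy_decreases_with_flip_noise(self):
        base = GeneratorConfig(B=3, t_b_range=(1, 1), t_bj_range=(2, 2),
                               n_symptoms=30, profile_size_range=(3, 3),
                               within_subclass_overlap=0.0,
                               gender_bias=(0.5, 0.5), n_per_disease=6,
                               flip_noise=0.0, seed=0)
        config = CascadeConfig(epochs=30, seed=1)
        means = []
        for noise in (0.02, 0.15, 0.3):
            accs = []
            for seed in (41, 42, 43):
                cfg = dataclasses.replace(base, flip_noise=noise, seed=seed)
                tax, prof = generate_taxonomy(cfg)
                records = generate_records(tax, prof, cfg)
                accs.append(loocv(records, tax, backend="svm", level="main",
                                  config=config).accuracy)
            means.append(np.mean(accs))
        assert means[0] >= means[1] >= means[2]


class TestWorkedExampleFixture:
    def test_taxonomy_record_and_expansion(self, worked_example):
        tax, record, entries = worked_example
        assert tax.code_base == 10
        assert tax.n_symptoms == 11
        assert tax.symptom_names[0] == "male"
        assert tax.codes_at("main") == list(range(101, 111))
        assert record.symptoms == (1, 1, 1, 1, 0, 0, 0, 0, 1, 0, 0)
        assert [e.code for e in entries] == [101, 1011, 10111]
        assert tax.name_of(10111) == "squamous cell carcinoma"
        assert tax.name_of(101) == "tumor disease"
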