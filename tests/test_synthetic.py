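"""The synthetic corpus generator: validity, determinism, imbalance."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from photorank.chem_io import validate_mapped_smiles, validate_record, write_dataset
from photorank.reaction_core import MappedReaction, extract_core
from photorank.synthetic import (
    GeneratorConfig,
    corpus_for_pretraining,
    default_templates,
    generate_dataset,
)


class TestConfigValidation:
    def test_bad_noise_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(label_noise=1.0)

    def test_bad_exponent_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(imbalance_exponent=0)

    def test_too_many_templates_rejected(self, registry):
        with pytest.raises(ValueError):
            generate_dataset(GeneratorConfig(n_templates=99, registry=registry))


class TestGeneratedRecords:
    def test_seed_determinism_byte_identical_files(self, tmp_path, registry):
        config = GeneratorConfig(n_records=60, seed=33, registry=registry)
        a, truth_a = generate_dataset(config)
        b, truth_b = generate_dataset(config)
        assert a == b
        assert truth_a.equals(truth_b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dataset(a, pa)
        write_dataset(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_zero_noise_single_template_all_labels_identical(self, registry):
        records, _ = generate_dataset(
            GeneratorConfig(n_records=30, n_templates=1, label_noise=0.0, registry=registry)
        )
        assert len({r.catalyst_label for r in records}) == 1

    def test_every_record_passes_validation(self, small_corpus, registry):
        for rec in small_corpus[0][:60]:
            validate_record(rec, registry)
            validate_mapped_smiles(rec.mapped_smiles)

    def test_label_noise_rate_matches_epsilon(self, registry):
        eps = 0.2
        records, truth = generate_dataset(
            GeneratorConfig(n_records=2000, label_noise=eps, seed=8, registry=registry)
        )
        flipped = np.mean(
            [r.catalyst_label != t for r, t in zip(records, truth["true_catalyst"])]
        )
        sigma = np.sqrt(eps * (1 - eps) / 2000)
        assert abs(flipped - eps) < 3 * sigma

    def test_ground_truth_aligns_with_records(self, small_corpus):
        records, truth = small_corpus
        assert list(truth["id"]) == [r.id for r in records]


class TestImbalance:
    def test_zipf_ratio_at_spec_parameters(self, registry):
        """Oracle-computed spread at exponent 1.1 over 31 classes.

        A pure Zipf law bounds the expected largest/smallest class ratio
        at 31^1.1 ~ 44, so the empirical ratio lands in the 30-50 range.
        """
        records, _ = generate_dataset(
            GeneratorConfig(
                n_records=10_000,
                n_templates=31,
                imbalance_exponent=1.1,
                label_noise=0.0,
                seed=13,
                registry=registry,
            )
        )
        counts = np.array(
            [sum(r.catalyst_label == n for r in records) for n in registry.names]
        )
        counts = counts[counts > 0]
        assert counts.max() / counts.min() > 30

    def test_steeper_exponent_exceeds_fifty(self, registry):
        records, _ = generate_dataset(
            GeneratorConfig(
                n_records=10_000,
                n_templates=31,
                imbalance_exponent=1.4,
                label_noise=0.0,
                seed=13,
                registry=registry,
            )
        )
        counts = np.array(
            [sum(r.catalyst_label == n for r in records) for n in registry.names]
        )
        counts = counts[counts > 0]
        assert counts.max() / counts.min() > 50

    def test_default_conditions_reach_literature_spread(self, registry):
        """Default exponent 1.7 emulates the >300-fold popularity spread."""
        records, _ = generate_dataset(
            GeneratorConfig(n_records=10_000, label_noise=0.0, seed=13, registry=registry)
        )
        counts = np.array(
            [sum(r.catalyst_label == n for r in records) for n in registry.names]
        )
        assert counts.max() / max(counts[counts > 0].min(), 1) > 100

    def test_counts_monotone_under_zipf_ordering(self, registry):
        records, truth = generate_dataset(
            GeneratorConfig(
                n_records=8000,
                n_templates=31,
                imbalance_exponent=1.3,
                label_noise=0.0,
                seed=17,
                registry=registry,
            )
        )
        counts = np.array(
            [sum(r.catalyst_label == n for r in records) for n in registry.names]
        )
        rho = spearmanr(np.arange(31), counts).statistic
        assert rho < -0.9  # popularity decays with registry rank


class TestPreferenceStructure:
    def test_bayes_ceiling_formula(self, registry):
        """Predicting each template's preferred catalyst scores 1-eps."""
        eps = 0.15
        records, truth = generate_dataset(
            GeneratorConfig(n_records=3000, label_noise=eps, seed=5, registry=registry)
        )
        hits = np.mean(
            [r.catalyst_label == t for r, t in zip(records, truth["true_catalyst"])]
        )
        assert abs(hits - (1 - eps)) < 3 * np.sqrt(eps * (1 - eps) / 3000)

    def test_confusable_pairs_mode_splits_mass(self, registry):
        templates = default_templates(registry, confusable_pairs=True)
        pref = templates[0].catalyst_preference
        assert np.isclose(pref.sum(), 1.0)
        assert (pref > 0).sum() == 2
        assert np.isclose(pref.max(), 0.7)


class TestPretrainingCorpus:
    def test_pair_count_and_disjoint_heldout(self, registry):
        config = GeneratorConfig(n_records=50, seed=9, registry=registry)
        train, heldout = corpus_for_pretraining(config)
        assert len(train) + len(heldout) == 50
        assert len(heldout) == 5

    def test_cores_reproducible_from_records(self, registry):
        config = GeneratorConfig(n_records=30, seed=9, registry=registry)
        train, heldout = corpus_for_pretraining(config)
        records, _ = generate_dataset(config)
        expected = [
            extract_core(MappedReaction.from_smiles(r.mapped_smiles)).core_smiles
            for r in records
        ]
        assert [c for c, _ in heldout + train] == expected[: len(heldout)] + expected[
            len(heldout) :
        ]
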