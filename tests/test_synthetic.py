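"""The synthetic-data generator: reproducibility, nulls, couplings, round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from attnov.arearatio import area_ratio_from_mask
from attnov.exceptions import ConfigurationError
from attnov.synthetic import (
    SimulationConfig,
    generate_dataset,
    simulate_idea_texts,
    simulate_masks,
    simulate_participants,
    simulate_ratings,
    simulate_reference_corpus,
)
from attnov.textnovelty import communication_burden, score_corpus


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, fieldname",
        [
            ({"n_participants": 3}, "n_participants"),
            ({"precision_phi": 0.0}, "precision_phi"),
            ({"zipf_exponent": -1.0}, "zipf_exponent"),
            ({"n_raters": 0}, "n_raters"),
            ({"image_size": 4}, "image_size"),
            ({"vocab_size": 5}, "vocab_size"),
        ],
    )
    def test_invalid_field_named_in_error(self, kwargs, fieldname):
        with pytest.raises(ConfigurationError, match=fieldname):
            SimulationConfig(**kwargs)


class TestParticipants:
    def test_seed_reproducibility(self):
        config = SimulationConfig(n_participants=50, seed=9)
        a = simulate_participants(config)
        b = simulate_participants(config)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate_participants(SimulationConfig(n_participants=50, seed=1))
        b = simulate_participants(SimulationConfig(n_participants=50, seed=2))
        assert not a.equals(b)

    def test_area_ratio_strictly_inside_unit_interval(self):
        table = simulate_participants(SimulationConfig(n_participants=500, seed=0))
        assert (table["area_ratio"] > 0).all() and (table["area_ratio"] < 1).all()

    def test_null_knowledge_effect_uncorrelated(self):
        config = SimulationConfig(n_participants=5000, seed=3, beta_knowledge=0.0)
        table = simulate_participants(config)
        r = np.corrcoef(table["test_score"], table["area_ratio"])[0, 1]
        assert abs(r) < 0.04

    def test_covariate_shapes(self):
        table = simulate_participants(SimulationConfig(n_participants=300, seed=4))
        assert table["gender"].isin([0, 1]).all()
        assert table["age"].between(20, 60).all()
        for col in ("n_speakers", "usage_frequency", "particularity", "self_knowledge"):
            assert table[col].between(1, 5).all()


class TestReferenceCorpus:
    def test_seed_reproducibility(self):
        config = SimulationConfig(seed=5)
        assert (
            simulate_reference_corpus(config).token_counts
            == simulate_reference_corpus(config).token_counts
        )

    def test_uniform_limit_at_zero_exponent(self):
        config = SimulationConfig(
            seed=6, zipf_exponent=0.0, vocab_size=100, n_reference_docs=1000, tokens_per_doc=100
        )
        ref = simulate_reference_corpus(config)
        counts = np.array([ref.token_counts.get(w, 0) for w in sorted(ref.token_counts)])
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, len(counts) - 1)
        assert p > 0.001

    def test_rank_frequency_slope_matches_exponent(self):
        s = 1.2
        config = SimulationConfig(
            seed=7, zipf_exponent=s, vocab_size=500, n_reference_docs=1000, tokens_per_doc=1000
        )
        ref = simulate_reference_corpus(config)
        counts = np.sort(np.array(list(ref.token_counts.values())))[::-1]
        top = counts[:200]  # head ranks, where sampling noise is small
        slope, *_ = stats.linregress(np.log(np.arange(1, len(top) + 1)), np.log(top))
        assert slope == pytest.approx(-s, abs=0.1)


class TestIdeaTexts:
    def test_zero_rare_weight_lowers_burden(self):
        config = SimulationConfig(n_participants=60, seed=8)
        participants = simulate_participants(config)
        ref = simulate_reference_corpus(config)
        plain = simulate_idea_texts(participants, ref, config, rare_weight=0.0)
        rare = simulate_idea_texts(participants, ref, config, rare_weight=1.0)
        cb_plain = np.mean(
            [communication_burden(d, ref).total for d in plain]
        )
        cb_rare = np.mean([communication_burden(d, ref).total for d in rare])
        assert cb_plain < cb_rare

    def test_null_area_coupling(self):
        config = SimulationConfig(n_participants=2000, seed=9, gamma_area=0.0)
        participants = simulate_participants(config)
        ref = simulate_reference_corpus(config)
        corpus = simulate_idea_texts(participants, ref, config)
        cb = np.array([communication_burden(d, ref).total for d in corpus])
        r = np.corrcoef(participants["area_ratio"], cb)[0, 1]
        assert abs(r) < 0.05

    def test_tfidf_and_cb_positively_correlated_on_study_like_data(self):
        config = SimulationConfig(n_participants=500, seed=10)
        dataset = generate_dataset(config)
        scores = score_corpus(dataset.idea_corpus, dataset.reference_corpus)
        rho = stats.spearmanr(scores["tfidf"], scores["cb"]).statistic
        assert rho > 0.5


class TestRatings:
    def test_zero_noise_makes_raters_identical(self):
        config = SimulationConfig(n_participants=40, seed=11, rater_noise_sd=0.0)
        participants = simulate_participants(config)
        ratings = simulate_ratings(participants, config)
        cols = [c for c in ratings.columns if c.startswith("rater_")]
        for col in cols[1:]:
            assert (ratings[col] == ratings[cols[0]]).all()

    def test_scores_are_ordinal_1_to_5(self):
        config = SimulationConfig(n_participants=200, seed=12)
        ratings = simulate_ratings(simulate_participants(config), config)
        vals = ratings.drop(columns="participant_id").to_numpy()
        assert vals.min() >= 1 and vals.max() <= 5
        assert np.issubdtype(vals.dtype, np.integer)

    def test_inter_rater_correlations_in_reported_envelope(self):
        config = SimulationConfig(n_participants=400, seed=13)
        ratings = simulate_ratings(simulate_participants(config), config)
        corr = ratings.drop(columns="participant_id").corr().to_numpy()
        off = corr[np.triu_indices_from(corr, k=1)]
        assert off.min() > 0
        # qualitative envelope of a 7-expert panel: moderate positive agreement
        assert 0.15 < off.mean() < 0.7


class TestMasks:
    def test_full_frame_for_ratio_one(self):
        config = SimulationConfig(n_participants=4, seed=14, image_size=32)
        participants = simulate_participants(config).head(1).assign(area_ratio=1.0)
        mask = simulate_masks(participants, config)[0]
        assert mask.mask.all()

    def test_quarter_ratio_pixel_count(self):
        config = SimulationConfig(n_participants=4, seed=15, image_size=100)
        participants = simulate_participants(config).head(1).assign(area_ratio=0.25)
        mask = simulate_masks(participants, config)[0]
        assert abs(int(mask.mask.sum()) - 2500) <= 1

    def test_round_trip_recovers_requested_ratio(self):
        config = SimulationConfig(n_participants=500, seed=16, image_size=100)
        participants = simulate_participants(config)
        masks = simulate_masks(participants, config)
        recovered = np.array([area_ratio_from_mask(m) for m in masks])
        err = np.abs(recovered - participants["area_ratio"].to_numpy())
        assert err.max() < 2 / config.image_size


class TestGenerateDataset:
    def test_bit_identical_for_same_config(self):
        config = SimulationConfig(n_participants=30, seed=17)
        a = generate_dataset(config)
        b = generate_dataset(config)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.ratings, b.ratings)
        assert [d.tokens for d in a.idea_corpus] == [d.tokens for d in b.idea_corpus]
        np.testing.assert_array_equal(a.masks[0].mask, b.masks[0].mask)

    def test_one_of_everything_per_participant(self):
        config = SimulationConfig(n_participants=25, seed=18)
        dataset = generate_dataset(config)
        assert dataset.idea_corpus.n_docs == 25
        assert len(dataset.masks) == 25
        assert len(dataset.ratings) == 25
        assert dataset.ratings.filter(like="rater_").shape[1] == config.n_raters

    def test_amazon_like_mode_masks_subset(self):
        config = SimulationConfig.amazon_like(n_participants=100, mask_fraction=0.4, seed=19)
        dataset = generate_dataset(config)
        assert len(dataset.masks) == 40
        assert dataset.idea_corpus.n_docs == 100

    def test_write_dataset_round_trip(self, tmp_path):
        from attnov.synthetic import write_dataset
        from attnov.textnovelty import read_corpus_jsonl, read_reference_corpus

        config = SimulationConfig(n_participants=10, seed=20, n_specialist_docs=5)
        dataset = generate_dataset(config)
        paths = write_dataset(dataset, tmp_path)
        back = pd.read_csv(paths["participants"])
        assert len(back) == 10
        corpus = read_corpus_jsonl(paths["ideas"])
        assert corpus.n_docs == 10
        ref = read_reference_corpus(paths["reference"])
        assert ref.total_tokens == dataset.reference_corpus.total_tokens
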