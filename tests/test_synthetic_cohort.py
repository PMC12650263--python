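import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from create_lab.blink_sebr import detect_blinks
from create_lab.errors import ValidationError
from create_lab.psychometrics import score_psqi
from create_lab.sentiment_text import text_features, tokenize
from create_lab.synthetic_cohort import (
    FILLER_WORDS,
    CohortConfig,
    generate_cohort,
    generate_eye_signal,
    generate_narrative,
    psqi_responses_for_global,
    sample_latent_traits,
)
from create_lab.sentiment_text import load_default_lexicon
from create_lab.wm_game import score_session


class TestConfigValidation:
    def test_non_psd_corr_rejected(self):
        bad = [
            [1.0, 0.9, 0.9, -0.9],
            [0.9, 1.0, -0.9, 0.9],
            [0.9, -0.9, 1.0, 0.9],
            [-0.9, 0.9, 0.9, 1.0],
        ]
        with pytest.raises(ValidationError, match="positive semi-definite"):
            CohortConfig(latent_corr=bad).validate()

    def test_asymmetric_corr_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = 0.5
        with pytest.raises(ValidationError, match="symmetric"):
            CohortConfig(latent_corr=bad).validate()

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValidationError, match="n_participants"):
            CohortConfig(n_participants=1).validate()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(good_sleeper_fraction=1.5).validate()


class TestLatentTraits:
    def test_identity_corr_pairwise_independence(self):
        z = sample_latent_traits(1000, np.eye(4), seed=0)
        for i in range(4):
            for j in range(i + 1, 4):
                rho = spearmanr(z[:, i], z[:, j]).statistic
                assert abs(rho) < 3 / math.sqrt(1000)

    def test_planted_correlation_recovered(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.6
        z = sample_latent_traits(2000, corr, seed=1)
        assert np.corrcoef(z[:, 0], z[:, 1])[0, 1] == pytest.approx(0.6, abs=0.06)


class TestDeterminism:
    def test_same_config_same_cohort(self):
        cfg = CohortConfig(n_participants=4, seed=77, eye_duration_s=10.0)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.truth == b.truth
        for pa, pb in zip(a.participants, b.participants):
            assert pa.trials == pb.trials
            assert pa.ratings == pb.ratings
            assert pa.psqi_responses == pb.psqi_responses
            assert pa.erq_responses == pb.erq_responses
            assert np.array_equal(pa.eye_pre.ratio, pb.eye_pre.ratio)
            assert np.array_equal(pa.eye_post.ratio, pb.eye_post.ratio)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_participants=3, seed=1, eye_duration_s=5.0))
        b = generate_cohort(CohortConfig(n_participants=3, seed=2, eye_duration_s=5.0))
        assert a.truth != b.truth


class TestEyeSignal:
    def test_rate_zero_silent(self):
        sig, onsets = generate_eye_signal(0, 30, 30, seed=0)
        assert onsets == []
        assert detect_blinks(sig, 30).blink_count == 0

    def test_planted_count_recovered(self):
        sig, onsets = generate_eye_signal(20, 60, 30, seed=3)
        assert len(onsets) == 20
        session = detect_blinks(sig, 30)
        assert session.blink_count == 20
        assert [a for a, _ in session.events] == onsets

    def test_same_seed_identical(self):
        s1, o1 = generate_eye_signal(10, 30, 30, seed=5)
        s2, o2 = generate_eye_signal(10, 30, 30, seed=5)
        assert np.array_equal(s1, s2)
        assert o1 == o2

    def test_rate_too_high_errors(self):
        with pytest.raises(ValidationError, match="too high"):
            generate_eye_signal(1000, 10, 30, seed=0)

    def test_negative_rate_errors(self):
        with pytest.raises(ValidationError):
            generate_eye_signal(-1, 10, 30, seed=0)


class TestNarrative:
    def test_neutral_target_all_filler(self):
        text = generate_narrative(0.0, 0.0, 9, seed=0)
        f = text_features(text)
        assert f.polarity == 0.0
        assert f.subjectivity == 0.0
        assert f.token_count == 9

    def test_positive_target_within_tolerance(self):
        text = generate_narrative(0.8, 0.85, 12, seed=1, tolerance=0.1)
        f = text_features(text)
        assert 0.7 <= f.polarity <= 0.9

    def test_token_count_round_trip(self):
        for n in (1, 2, 5, 12, 30):
            text = generate_narrative(0.3, 0.5, n, seed=n)
            assert len(tokenize(text)) == n

    def test_negative_target(self):
        text = generate_narrative(-0.6, 0.8, 15, seed=2)
        f = text_features(text)
        assert f.polarity == pytest.approx(-0.6, abs=0.12)
        assert f.subjectivity == pytest.approx(0.8, abs=0.12)

    def test_unreachable_marginal_errors_with_range(self):
        with pytest.raises(ValidationError, match="feasible"):
            generate_narrative(0.99, 0.5, 10, seed=0)

    def test_unreachable_joint_errors(self):
        # very positive polarity with near-zero subjectivity has no support
        with pytest.raises(ValidationError, match="unreachable|feasible"):
            generate_narrative(0.9, 0.02, 10, seed=0, tolerance=0.05)

    def test_filler_words_never_score(self):
        lex = load_default_lexicon()
        assert not set(FILLER_WORDS) & set(lex.entries)
        assert not set(FILLER_WORDS) & set(lex.negators)

    def test_deterministic(self):
        assert generate_narrative(0.4, 0.6, 10, seed=9) == generate_narrative(0.4, 0.6, 10, seed=9)


class TestPSQIGeneration:
    @pytest.mark.parametrize("g", range(0, 22))
    def test_inversion_round_trip(self, g):
        assert score_psqi(psqi_responses_for_global(g)).global_score == g


class TestCohortStructure:
    def test_bundles_complete_and_truth_aligned(self, small_cohort):
        pids = [p.participant_id for p in small_cohort.participants]
        assert len(pids) == len(set(pids)) == 12
        assert set(small_cohort.truth["participants"]) == set(pids)
        for part in small_cohort.participants:
            assert len(part.trials) == small_cohort.config.n_trials
            assert len(part.ratings) == small_cohort.config.n_stimuli
            assert len(part.psqi_responses) == 19
            assert len(part.erq_responses) == 10
            assert part.eye_pre.ratio.size > 0 and part.eye_post.ratio.size > 0

    def test_planted_blink_counts_recovered_exactly(self, small_cohort):
        for part in small_cohort.participants:
            truth = small_cohort.truth["participants"][part.participant_id]
            for phase, sig in (("pre", part.eye_pre), ("post", part.eye_post)):
                session = detect_blinks(sig.ratio, sig.fps)
                assert session.blink_count == truth["blink_counts"][phase]
                assert [a for a, _ in session.events] == truth["blink_onsets"][phase]

    def test_psqi_matches_planted_group(self, small_cohort):
        for part in small_cohort.participants:
            truth = small_cohort.truth["participants"][part.participant_id]
            scored = score_psqi(part.psqi_responses)
            assert scored.global_score == truth["psqi_global_target"]
            assert (scored.group == "Good") == truth["good_sleeper"]

    def test_good_sleeper_fraction_converges(self):
        cfg = CohortConfig(
            n_participants=150, seed=5, eye_duration_s=2.0, n_stimuli=1, n_trials=5
        )
        cohort = generate_cohort(cfg)
        frac = np.mean(
            [t["good_sleeper"] for t in cohort.truth["participants"].values()]
        )
        # binomial 3*SD tolerance at n=150 around 1/3
        tol = 3 * math.sqrt((1 / 3) * (2 / 3) / 150)
        assert abs(frac - 1 / 3) <= tol

    def test_narratives_hit_planted_targets(self, small_cohort):
        for part in small_cohort.participants:
            truth = small_cohort.truth["participants"][part.participant_id]
            targets = truth["text_targets"]
            for rating in part.ratings:
                f = text_features(rating.comment)
                tol = small_cohort.config.text_params.tolerance + 1e-9
                assert abs(f.polarity - targets["polarity"]) <= tol
                assert abs(f.subjectivity - targets["subjectivity"]) <= tol


class TestPlantedCorrelation:
    def test_attenuated_spearman_matches_large_n_oracle(self):
        # Frozen oracle: a 1e5-row simulation of the same monotone maps
        # (capacity = 9 + 2.5 z, 40-trial session, ERQ ordinal items) under
        # planted latent rho(wm, er) = 0.6 gave Spearman 0.5426.
        oracle = 0.5426
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.6
        cfg = CohortConfig(
            n_participants=1000,
            latent_corr=corr,
            seed=31,
            eye_duration_s=2.0,
            n_stimuli=1,
        )
        cohort = generate_cohort(cfg)
        mean_scores = [score_session(p.trials).mean_score for p in cohort.participants]
        from create_lab.psychometrics import score_erq

        er_totals = [score_erq(p.erq_responses).total for p in cohort.participants]
        rho = spearmanr(mean_scores, er_totals).statistic
        assert rho == pytest.approx(oracle, abs=0.10)

    def test_copula_sign_preservation(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = -0.5
        cfg = CohortConfig(
            n_participants=400,
            latent_corr=corr,
            seed=8,
            eye_duration_s=2.0,
            n_stimuli=1,
        )
        cohort = generate_cohort(cfg)
        from create_lab.psychometrics import score_erq

        mean_scores = [score_session(p.trials).mean_score for p in cohort.participants]
        er_totals = [score_erq(p.erq_responses).total for p in cohort.participants]
        assert spearmanr(mean_scores, er_totals).statistic < 0
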