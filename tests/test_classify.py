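"""Database matching: similarity score, 6-of-8 rule, verdicts, database build."""

import numpy as np
import pytest

from enosekit.classify import (UNIDENTIFIED, OdorDatabase, ReferenceRecord,
                               build_database, channel_similarity,
                               match_database, match_record, success_rate)
from enosekit.features import GradientProfile, profile_of_frame
from enosekit.sim import BUILTIN_SPECS, generate_event


def make_profile(values, window=10, label=None, role="query"):
    values = np.asarray(values, dtype=float)
    epochs = np.arange(1, values.shape[1] + 1) * window
    channels = tuple(f"ch{i}" for i in range(8))
    return GradientProfile(channels=channels, epochs=epochs, values=values,
                           window=window, role=role, label=label)


def record_from_values(values, label="ref", **kw):
    return ReferenceRecord(label=label,
                           signature=make_profile(values, role="reference", **kw))


class TestChannelSimilarity:
    def test_identical_nonzero_gradients(self):
        assert channel_similarity(0.3, 0.3) == 1.0

    def test_sign_mismatch_scores_zero(self):
        assert channel_similarity(0.1, -0.1) == 0.0

    def test_relative_difference(self):
        assert channel_similarity(0.08, 0.10) == pytest.approx(0.8)

    def test_near_zero_matches_only_near_zero(self):
        assert channel_similarity(1e-9, 1e-8) == 1.0
        assert channel_similarity(1e-9, 0.5) == 0.0

    def test_score_always_in_unit_interval(self, rng):
        for _ in range(200):
            g1, g2 = rng.normal(size=2) * 0.01
            assert 0.0 <= channel_similarity(g1, g2) <= 1.0


class TestMatchRecord:
    def test_self_match_is_8_of_8(self, rng):
        values = rng.uniform(0.01, 0.1, size=(8, 5))
        record = record_from_values(values)
        result = match_record(make_profile(values), record)
        assert result.n_matched == 8 and result.success

    def test_exactly_six_matching_channels_succeeds(self, rng):
        ref = rng.uniform(0.05, 0.1, size=(8, 4))
        query = ref.copy()
        query[6] = -ref[6]  # sign flip -> similarity 0
        query[7] = -ref[7]
        result = match_record(make_profile(query), record_from_values(ref))
        assert result.n_matched == 6 and result.success

    def test_five_matching_channels_fails(self, rng):
        ref = rng.uniform(0.05, 0.1, size=(8, 4))
        query = ref.copy()
        for c in (5, 6, 7):
            query[c] = -ref[c]
        result = match_record(make_profile(query), record_from_values(ref))
        assert result.n_matched == 5 and not result.success

    def test_one_bad_epoch_fails_the_whole_channel(self, rng):
        ref = rng.uniform(0.05, 0.1, size=(8, 6))
        query = ref.copy()
        query[0, 3] = -ref[0, 3]
        result = match_record(make_profile(query), record_from_values(ref))
        assert not result.channel_match[0]
        assert result.n_matched == 7

    def test_threshold_monotonicity(self, rng):
        ref = rng.uniform(0.01, 0.1, size=(8, 5))
        query = ref * rng.uniform(0.7, 1.3, size=(8, 5))
        matched = [match_record(make_profile(query), record_from_values(ref),
                                sim_threshold=th).n_matched
                   for th in (0.5, 0.7, 0.8, 0.9, 0.99)]
        assert matched == sorted(matched, reverse=True)

    def test_min_channels_monotonicity(self, rng):
        ref = rng.uniform(0.01, 0.1, size=(8, 5))
        query = ref * rng.uniform(0.75, 1.25, size=(8, 5))
        outcomes = [match_record(make_profile(query), record_from_values(ref),
                                 min_channels=mc).success
                    for mc in range(9)]
        # once failure appears it never turns back into success
        assert all(not (not a and b) for a, b in zip(outcomes, outcomes[1:]))

    def test_strict_inequality_flips_the_boundary(self):
        # binary-exact similarity: 1 - 0.125/0.5 = 0.75 at every epoch
        ref = np.full((8, 2), 0.5)
        query = np.full((8, 2), 0.375)
        rec = record_from_values(ref)
        assert match_record(make_profile(query), rec, sim_threshold=0.75,
                            strict=False).success
        assert not match_record(make_profile(query), rec, sim_threshold=0.75,
                                strict=True).success

    def test_window_mismatch_rejected(self, rng):
        ref = record_from_values(rng.uniform(0.01, 0.1, size=(8, 4)))
        query = make_profile(rng.uniform(0.01, 0.1, size=(8, 4)), window=5)
        with pytest.raises(ValueError):
            match_record(query, ref)


class TestMatchDatabase:
    def test_own_signature_ranks_first(self, rng):
        values = rng.uniform(0.01, 0.1, size=(8, 5))
        other = rng.uniform(0.2, 0.4, size=(8, 5))
        db = OdorDatabase(records=[record_from_values(other, "other"),
                                   record_from_values(values, "mine")], window=10)
        ranked, verdict = match_database(make_profile(values), db)
        assert verdict == "mine"
        assert ranked[0].label == "mine" and ranked[0].n_matched == 8

    def test_all_records_failing_gives_unidentified(self, rng):
        values = rng.uniform(0.01, 0.1, size=(8, 5))
        db = OdorDatabase(records=[record_from_values(-values, "neg")], window=10)
        _, verdict = match_database(make_profile(values), db)
        assert verdict == UNIDENTIFIED

    def test_empty_database_rejected(self, rng):
        with pytest.raises(ValueError):
            match_database(make_profile(rng.random((8, 3))),
                           OdorDatabase(records=[], window=10))


class TestSuccessRate:
    def test_all_correct(self):
        assert success_rate(["a", "b"], ["a", "b"]) == 100.0

    def test_nineteen_of_twenty(self):
        verdicts = ["a"] * 19 + ["b"]
        assert success_rate(verdicts, ["a"] * 20) == pytest.approx(95.0)

    def test_random_verdicts_near_half_for_two_balanced_classes(self):
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(1000):
            truths = ["a", "b"] * 5
            verdicts = rng.choice(["a", "b"], size=10)
            rates.append(success_rate(verdicts, truths))
        # mean of Binomial(10, 0.5)/10 over 1000 trials
        assert abs(np.mean(rates) - 50.0) < 4.3 * 100 * np.sqrt(0.25 / 10000)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            success_rate([], [])


class TestBuildDatabase:
    def test_single_frame_signature_matches_direct_profile(self):
        spec = BUILTIN_SPECS["fresh_fish"]
        frame = generate_event(spec, duration=200, seed=0)
        db = build_database({spec.label: [frame]}, 10, spec.saturation, seed=0)
        direct = profile_of_frame(frame, 10, spec.saturation)
        assert np.allclose(db.records[0].signature.values, direct.values)

    def test_duplicated_frames_same_signature(self):
        spec = BUILTIN_SPECS["fresh_meat"]
        frame = generate_event(spec, duration=200, seed=1)
        db1 = build_database({spec.label: [frame]}, 10, spec.saturation, seed=0)
        db3 = build_database({spec.label: [frame] * 3}, 10, spec.saturation, seed=0)
        assert np.allclose(db1.records[0].signature.values,
                           db3.records[0].signature.values)

    def test_averaged_signature_closer_to_noiseless_profile(self):
        from enosekit.sim import SensorFrame
        spec = BUILTIN_SPECS["decayed_fish_day1"]
        frames = [generate_event(spec, duration=300, seed=s) for s in range(30)]
        clean = SensorFrame(times=np.arange(300.0),
                            values=np.clip(spec.noiseless_curve(300), 0,
                                           np.asarray(spec.saturation)[:, None]),
                            label=spec.label)
        clean_profile = profile_of_frame(clean, 10, spec.saturation)
        db = build_database({spec.label: frames}, 10, spec.saturation, seed=0)
        db_dist = np.linalg.norm(db.records[0].signature.values - clean_profile.values)
        single_dists = [np.linalg.norm(
            profile_of_frame(f, 10, spec.saturation).values - clean_profile.values)
            for f in frames]
        assert db_dist < min(single_dists)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            build_database({"x": []}, 10, 5.0)
        with pytest.raises(ValueError):
            build_database({}, 10, 5.0)

    def test_database_json_round_trip(self, tmp_path):
        from enosekit import io
        spec = BUILTIN_SPECS["fresh_fish"]
        frame = generate_event(spec, duration=150, seed=0)
        db = build_database({spec.label: [frame]}, 10, spec.saturation, seed=0)
        path = tmp_path / "db.json"
        io.write_database(db, path)
        loaded = io.read_database(path)
        assert loaded.labels() == db.labels()
        assert np.allclose(loaded.records[0].signature.values,
                           db.records[0].signature.values)
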