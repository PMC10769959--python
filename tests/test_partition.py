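import numpy as np
import pytest
from hypothesis import given, strategies as st

from eegleakage.partition import (
    SplitSpec,
    TimeBasedSplitter,
    TransferRateSplitter,
    assign_folds,
    combined_split,
    leakage_report,
    subject_independent_split,
    time_based_split,
    video_independent_split,
)
from eegleakage.preprocess import SegmentSet
from eegleakage.simulate import GeneratorConfig, generate
from eegleakage.preprocess import prepare


def make_segments(S, V, per_trial, T=1.0, f=4, D=None):
    """Synthetic index-only segment table (tiny constant signals)."""
    D = D if D is not None else per_trial * T
    n = S * V * per_trial
    subj = np.repeat(np.arange(1, S + 1), V * per_trial)
    vid = np.tile(np.repeat(np.arange(1, V + 1), per_trial), S)
    start = np.tile(np.arange(per_trial) * T, S * V)
    rng = np.random.default_rng(0)
    return SegmentSet(
        X=rng.normal(size=(n, 2, int(T * f))).astype(np.float32),
        y=rng.integers(0, 2, n),
        subject=subj,
        video=vid,
        start_s=start,
        T=T,
        overlap=0.0,
        label_dimension="valence",
        f=f,
        D=int(D),
    )


class TestAssignFolds:
    def test_32_subjects_5_folds_sizes(self):
        fa = assign_folds(range(1, 33), 5, seed=0)
        assert sorted(len(f) for f in fa.folds) == [6, 6, 6, 7, 7]

    def test_40_videos_5_folds_all_8(self):
        fa = assign_folds(range(1, 41), 5, seed=0)
        assert [len(f) for f in fa.folds] == [8] * 5

    def test_deterministic(self):
        a = assign_folds(range(10), 3, seed=5)
        b = assign_folds(range(10), 3, seed=5)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_disjoint_and_exhaustive(self):
        fa = assign_folds(range(1, 23), 4, seed=2)
        ids = np.concatenate(fa.folds)
        assert sorted(ids.tolist()) == list(range(1, 23))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(range(3), 4, seed=0)


class TestTransferCounting:
    def test_printed_arithmetic_example(self):
        # N=1000 segments, k=5 -> fold of 200; F=4% -> 40 test segments;
        # pool R = 160; beta=0.2 transfers 32 = 3.2% of N
        segs = make_segments(S=10, V=10, per_trial=10)
        spec = SplitSpec(mode="subject_independent", k=5, F=0.04, beta=0.2,
                         seed=3)
        part = subject_independent_split(segs, None, 0, spec)
        assert len(segs) == 1000
        assert len(part.test_idx) == 40
        assert part.R == pytest.approx(0.16)
        assert len(part.transfer_idx) == 32
        rep = leakage_report(part, segs)
        assert rep["transfer_fraction_of_total"] == pytest.approx(0.032)

    def test_fold_share_identity(self):
        # with k=5 each fold holds 20% of segments and R = 20% - F
        segs = make_segments(S=10, V=4, per_trial=5)
        for F in (0.04, 0.16):
            spec = SplitSpec(k=5, F=F, beta=0.0, seed=1)
            part = subject_independent_split(segs, None, 2, spec)
            assert part.R == pytest.approx(0.20 - F)

    def test_f_larger_than_fold_share_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            SplitSpec(k=5, F=0.25).validate()


class TestSubjectIndependent:
    def test_beta_zero_has_no_subject_overlap(self):
        segs = make_segments(S=6, V=5, per_trial=6)
        spec = SplitSpec(k=5, F=0.04, beta=0.0, seed=11)
        for fold in range(5):
            part = subject_independent_split(segs, None, fold, spec)
            rep = leakage_report(part, segs)
            assert rep["subject_overlap"] == 0

    def test_test_set_fixed_across_beta(self):
        segs = make_segments(S=6, V=5, per_trial=6)
        tests = []
        for beta in (0.0, 0.2, 0.4, 0.6, 0.8):
            spec = SplitSpec(k=5, F=0.04, beta=beta, seed=11)
            part = subject_independent_split(segs, None, 1, spec)
            tests.append(part.test_idx)
        for t in tests[1:]:
            np.testing.assert_array_equal(t, tests[0])

    def test_transfer_sets_are_nested_in_beta(self):
        segs = make_segments(S=6, V=5, per_trial=6)
        prev = None
        for beta in (0.2, 0.4, 0.6, 0.8):
            spec = SplitSpec(k=5, F=0.04, beta=beta, seed=11)
            part = subject_independent_split(segs, None, 0, spec)
            cur = set(part.transfer_idx.tolist())
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_transfer_segments_come_from_fold_subjects(self):
        segs = make_segments(S=6, V=5, per_trial=6)
        spec = SplitSpec(k=5, F=0.04, beta=0.5, seed=11)
        part = subject_independent_split(segs, None, 0, spec)
        splitter = TransferRateSplitter(spec)
        fold_subjects = set(splitter.folds(segs).folds[0].tolist())
        assert set(segs.subject[part.transfer_idx]) <= fold_subjects
        # and the transfer is disjoint from the evaluated test set
        assert not set(part.transfer_idx) & set(part.test_idx)

    def test_loso_when_k_equals_subject_count(self):
        segs = make_segments(S=6, V=5, per_trial=6)
        spec = SplitSpec(k=6, F=1.0 / 6 / 2, beta=0.0, seed=0)
        splitter = TransferRateSplitter(spec)
        folds = splitter.folds(segs)
        assert all(len(f) == 1 for f in folds.folds)
        for fold in range(6):
            part = splitter.partition(segs, fold, folds)
            held_out = folds.folds[fold][0]
            assert held_out not in set(segs.subject[part.train_idx])


class TestVideoIndependent:
    def test_beta_zero_has_no_video_overlap_but_full_subject_overlap(self):
        segs = make_segments(S=4, V=10, per_trial=4)
        spec = SplitSpec(mode="video_independent", k=5, F=0.04, beta=0.0,
                         seed=2)
        part = video_independent_split(segs, None, 0, spec)
        rep = leakage_report(part, segs)
        assert rep["video_overlap"] == 0
        # every subject present in test is also in training (the leakage
        # mechanism of stimulus-level splits)
        assert set(segs.subject[part.test_idx]) <= set(
            segs.subject[part.train_idx]
        )

    def test_test_size_arithmetic(self):
        segs = make_segments(S=4, V=10, per_trial=4)
        spec = SplitSpec(mode="video_independent", k=5, F=0.04, seed=2)
        part = video_independent_split(segs, None, 3, spec)
        assert len(part.test_idx) == round(0.04 * len(segs))


class TestTimeBased:
    def _segs(self):
        ds = generate(GeneratorConfig(S=2, V=3, C=2, f=8, D=60, seed=0))
        return prepare(ds, T=1.0)

    def test_last_fifth_is_the_test_window(self):
        segs = self._segs()
        spec = SplitSpec(mode="time_based", rho=1.0, test_tail=0.2, seed=0)
        part = time_based_split(segs, spec)
        # 12 test segments per trial, 6 trials
        assert len(part.test_idx) == 12 * 6
        assert segs.start_s[part.test_idx].min() == pytest.approx(48.0)

    def test_forward_rho_04_gives_19_segments_per_trial(self):
        segs = self._segs()
        spec = SplitSpec(mode="time_based", rho=0.4, direction="forward",
                         seed=0)
        part = time_based_split(segs, spec)
        # train window [0, 0.4 * 48 = 19.2) -> 19 one-second segments
        assert len(part.train_idx) == 19 * 6
        assert segs.start_s[part.train_idx].max() == pytest.approx(18.0)

    def test_backward_window_position(self):
        segs = self._segs()
        spec = SplitSpec(mode="time_based", rho=0.4, direction="backward",
                         seed=0)
        part = time_based_split(segs, spec)
        # window [48*0.6 = 28.8, 48) -> starts 29..47
        assert segs.start_s[part.train_idx].min() == pytest.approx(29.0)
        assert len(part.train_idx) == 19 * 6

    def test_rho_one_forward_equals_backward(self):
        segs = self._segs()
        fwd = time_based_split(
            segs, SplitSpec(mode="time_based", rho=1.0, direction="forward")
        )
        bwd = time_based_split(
            segs, SplitSpec(mode="time_based", rho=1.0, direction="backward")
        )
        np.testing.assert_array_equal(fwd.train_idx, bwd.train_idx)

    def test_adjacent_segments_give_zero_temporal_gap(self):
        segs = self._segs()
        part = time_based_split(segs, SplitSpec(mode="time_based", rho=1.0))
        rep = leakage_report(part, segs)
        assert rep["min_temporal_gap_s"] == 0.0
        assert rep["subject_overlap"] > 0 and rep["video_overlap"] > 0

    def test_window_too_short_for_segment_raises(self):
        ds = generate(GeneratorConfig(S=1, V=2, C=2, f=8, D=20, seed=0))
        segs = prepare(ds, T=4.0)
        spec = SplitSpec(mode="time_based", rho=0.2, seed=0)  # 3.2 s window
        with pytest.raises(ValueError, match="empty training set"):
            time_based_split(segs, spec)


class TestCombined:
    def test_rho_one_degenerates_to_subject_independent(self):
        segs = make_segments(S=6, V=5, per_trial=8)
        for beta in (0.0, 0.4):
            si = subject_independent_split(
                segs, None, 1, SplitSpec(k=5, F=0.04, beta=beta, seed=5)
            )
            co = combined_split(
                segs, None, 1,
                SplitSpec(mode="combined", k=5, F=0.04, beta=beta, rho=1.0,
                          seed=5),
            )
            np.testing.assert_array_equal(si.train_idx, co.train_idx)
            np.testing.assert_array_equal(si.test_idx, co.test_idx)
            np.testing.assert_array_equal(si.transfer_idx, co.transfer_idx)

    def test_training_restricted_to_leading_window(self):
        segs = make_segments(S=6, V=5, per_trial=10)  # D = 10 s, T = 1 s
        spec = SplitSpec(mode="combined", k=5, F=0.04, beta=0.8, rho=0.2,
                         seed=5)
        part = combined_split(segs, None, 0, spec)
        assert segs.start_s[part.train_idx].max() <= 0.2 * segs.D - segs.T
        # the fixed test set is NOT time restricted
        assert segs.start_s[part.test_idx].max() > 0.2 * segs.D

    def test_scarce_training_at_small_rho_with_long_segments(self):
        ds = generate(GeneratorConfig(S=3, V=4, C=2, f=8, D=60, seed=1))
        segs = prepare(ds, T=4.0)
        spec = SplitSpec(mode="combined", k=3, F=0.04, beta=0.0, rho=0.2,
                         seed=2)
        part = combined_split(segs, None, 0, spec)
        # per-trial trainable segments inside [0, 12 s): starts 0, 4, 8
        trains_per_trial = {}
        for i in part.train_idx:
            key = (segs.subject[i], segs.video[i])
            trains_per_trial[key] = trains_per_trial.get(key, 0) + 1
        assert set(trains_per_trial.values()) == {3}

    def test_beta_zero_keeps_subject_disjointness(self):
        segs = make_segments(S=6, V=5, per_trial=10)
        spec = SplitSpec(mode="combined", k=5, F=0.04, beta=0.0, rho=0.6,
                         seed=5)
        part = combined_split(segs, None, 2, spec)
        assert leakage_report(part, segs)["subject_overlap"] == 0


@given(
    mode=st.sampled_from(["subject_independent", "video_independent"]),
    beta=st.sampled_from([0.0, 0.2, 0.4, 0.6, 0.8]),
    fold=st.integers(0, 4),
    seed=st.integers(0, 1000),
)
def test_train_test_always_disjoint(mode, beta, fold, seed):
    segs = make_segments(S=6, V=5, per_trial=4)
    spec = SplitSpec(mode=mode, k=5, F=0.04, beta=beta, seed=seed)
    part = TransferRateSplitter(spec).partition(segs, fold)
    assert not set(part.train_idx) & set(part.test_idx)
    assert set(part.transfer_idx) <= set(part.train_idx)


def test_splitter_iterates_all_folds(small_segments):
    spec = SplitSpec(k=5, F=0.04, beta=0.2, seed=3)
    pairs = list(TransferRateSplitter(spec).split(small_segments))
    assert len(pairs) == 5
    covered = np.sort(np.concatenate([te for _, te in pairs]))
    assert len(covered) == len(set(covered.tolist()))


def test_time_based_splitter_single_split(small_segments):
    spec = SplitSpec(mode="time_based", rho=0.5, seed=0)
    pairs = list(TimeBasedSplitter(spec).split(small_segments))
    assert len(pairs) == 1
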