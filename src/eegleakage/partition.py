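"""Train/test partition construction with a controlled data transfer rate.

Three split families, each matching a practical BCI evaluation scenario:

* **subject-independent** — cross-validation folds are disjoint subject
  sets (affective decoding; ``k = S`` gives leave-one-subject-out);
* **video-independent** — folds are disjoint stimulus-video sets
  (affective annotation);
* **time-based** — the last ``test_tail`` fraction of every trial is the
  test set and training segments are drawn from earlier (forward) or later
  (backward) parts of the remaining signal, controlled by the sequence
  ratio ``rho``.

The *data transfer rate* ``beta`` quantifies controlled leakage: a fixed
evaluated test set of size ``round(F * N)`` is drawn once per fold
(independently of ``beta``), and ``beta`` of the fold's remaining pool
``R`` is "transferred" into the training partition. Because the test set
never varies with ``beta``, any performance change along a ``beta`` sweep
is attributable to leakage alone. Transfer draws are nested (a shared
per-fold permutation, prefix per ``beta``), so the training sets along a
sweep differ only by added segments.

The splitter classes follow the scikit-learn cross-validator idiom
(``split`` yields train/test index arrays); the module-level functions are
thin wrappers kept for a functional call style.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from ._seeds import spawn_rng
from .preprocess import SegmentSet

__all__ = [
    "SplitSpec",
    "FoldAssignment",
    "Partition",
    "assign_folds",
    "TransferRateSplitter",
    "TimeBasedSplitter",
    "subject_independent_split",
    "video_independent_split",
    "time_based_split",
    "combined_split",
    "leakage_report",
]

MODES = ("subject_independent", "video_independent", "time_based", "combined")


def _round_half_even(x: float) -> int:
    """Banker's rounding; keeps |test| and |transfer| reproducible."""
    return int(round(x))


@dataclass
class SplitSpec:
    """Declarative description of one split configuration."""

    mode: str = "subject_independent"
    k: int = 5  # fold count; k = S is leave-one-subject-out
    F: float = 0.04  # fixed test-set size, ratio of total segment count
    beta: float = 0.0  # transfer rate in [0, 1]
    rho: float = 1.0  # sequence ratio in (0, 1]
    direction: str = "forward"  # or "backward"
    test_tail: float = 0.2  # trial fraction reserved for testing (time-based)
    transfer_unit: str = "segment"  # or "trial"
    stratify_test_by: str | None = None  # None or "subject"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")
        if not 0.0 <= self.test_tail <= 1.0:
            raise ValueError("test_tail must lie in [0, 1]")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if self.mode in ("subject_independent", "video_independent", "combined"):
            if self.k < 1:
                raise ValueError("k must be >= 1")
            if self.F > 1.0 / self.k + 1e-12:
                raise ValueError(
                    f"F={self.F} exceeds the fold share 1/k={1.0 / self.k:.4f}; "
                    "the fixed test set must fit inside one fold"
                )
        if self.transfer_unit not in ("segment", "trial"):
            raise ValueError("transfer_unit must be 'segment' or 'trial'")


@dataclass
class FoldAssignment:
    """Disjoint, exhaustive entity-to-fold mapping (sizes differ by <= 1)."""

    entity_kind: str  # "subject" or "video"
    folds: list[np.ndarray]  # fold index -> entity id array

    def validate(self, entity_ids: np.ndarray) -> None:
        all_ids = np.concatenate(self.folds) if self.folds else np.array([])
        if len(all_ids) != len(set(all_ids.tolist())):
            raise ValueError("fold entity sets overlap")
        if set(all_ids.tolist()) != set(np.asarray(entity_ids).tolist()):
            raise ValueError("folds do not cover all entities")
        sizes = [len(fo) for fo in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than 1")


@dataclass
class Partition:
    """Realised train/test split for one fold.

    ``transfer_idx`` records which training segments were moved in from the
    test fold's pool (always a subset of ``train_idx``); ``R`` is the
    realised pool ratio |pool| / N.
    """

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    transfer_idx: np.ndarray
    R: float
    spec: SplitSpec = field(default_factory=SplitSpec)

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")
        if np.setdiff1d(self.transfer_idx, self.train_idx).size:
            raise ValueError("transfer indices must be training indices")


def assign_folds(entity_ids, k: int, seed: int) -> FoldAssignment:
    """Deal a seeded random permutation of entities round-robin into k folds.

    With 32 subjects and k=5 this yields fold sizes {7, 7, 6, 6, 6}.
    """
    entity_ids = np.asarray(sorted(entity_ids))
    if k > len(entity_ids):
        raise ValueError(
            f"k={k} exceeds the number of entities ({len(entity_ids)})"
        )
    rng = spawn_rng(seed, "folds")
    perm = rng.permutation(entity_ids)
    folds = [perm[i::k].copy() for i in range(k)]
    fa = FoldAssignment(entity_kind="", folds=folds)
    fa.validate(entity_ids)
    return fa


def _segments_in_window(
    segset: SegmentSet, idx: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    """Subset of ``idx`` whose segments lie fully inside [lo, hi) seconds."""
    starts = segset.start_s[idx]
    return idx[(starts >= lo - 1e-9) & (starts + segset.T <= hi + 1e-9)]


class TransferRateSplitter:
    """Entity-disjoint k-fold splitter with a data transfer rate.

    Handles the subject-independent, video-independent and combined
    (subject-independent x forward temporal restriction) modes. Iterating
    :meth:`split` yields plain (train, test) index pairs in the
    scikit-learn cross-validator style; :meth:`partition` returns the full
    bookkeeping for one fold.
    """

    def __init__(self, spec: SplitSpec):
        spec.validate()
        if spec.mode == "time_based":
            raise ValueError("use TimeBasedSplitter for time-based splits")
        self.spec = spec

    # -- fold machinery -------------------------------------------------
    def entity_kind(self) -> str:
        return "video" if self.spec.mode == "video_independent" else "subject"

    def folds(self, segset: SegmentSet) -> FoldAssignment:
        kind = self.entity_kind()
        ids = (
            np.unique(segset.video)
            if kind == "video"
            else np.unique(segset.subject)
        )
        fa = assign_folds(ids, self.spec.k, self.spec.seed)
        fa.entity_kind = kind
        return fa

    def get_n_splits(self, segset: SegmentSet | None = None) -> int:
        return self.spec.k

    # -- draws ----------------------------------------------------------
    def _fold_segments(
        self, segset: SegmentSet, folds: FoldAssignment, fold_idx: int
    ) -> np.ndarray:
        entities = folds.folds[fold_idx]
        values = (
            segset.video if folds.entity_kind == "video" else segset.subject
        )
        return np.flatnonzero(np.isin(values, entities))

    def _draw_test(
        self, segset: SegmentSet, fold_segments: np.ndarray, fold_idx: int
    ) -> np.ndarray:
        """Fixed test draw, seeded by (seed, fold) only — never by beta."""
        spec = self.spec
        n_test = _round_half_even(spec.F * len(segset))
        if n_test > len(fold_segments):
            raise ValueError(
                f"F={spec.F} requests {n_test} test segments but fold "
                f"{fold_idx} holds only {len(fold_segments)}"
            )
        rng = spawn_rng(spec.seed, "test", fold_idx)
        if spec.stratify_test_by == "subject":
            subjects = np.unique(segset.subject[fold_segments])
            parts = []
            # proportional allocation, remainder to the largest groups
            quota = np.array(
                [
                    (segset.subject[fold_segments] == s).sum()
                    for s in subjects
                ],
                dtype=float,
            )
            quota = quota / quota.sum() * n_test
            counts = np.floor(quota).astype(int)
            remainder = n_test - counts.sum()
            order = np.argsort(quota - counts)[::-1]
            counts[order[:remainder]] += 1
            for s, c in zip(subjects, counts):
                pool_s = fold_segments[segset.subject[fold_segments] == s]
                parts.append(rng.choice(pool_s, size=c, replace=False))
            return np.sort(np.concatenate(parts))
        return np.sort(rng.choice(fold_segments, size=n_test, replace=False))

    def _draw_transfer(
        self,
        segset: SegmentSet,
        pool: np.ndarray,
        fold_idx: int,
    ) -> np.ndarray:
        """Nested transfer draw: shared permutation, prefix per beta."""
        spec = self.spec
        rng = spawn_rng(spec.seed, "transfer", fold_idx)
        if spec.transfer_unit == "trial":
            keys = segset.subject[pool] * (segset.video.max() + 1) + (
                segset.video[pool]
            )
            trials = np.unique(keys)
            perm_trials = rng.permutation(trials)
            order = np.concatenate(
                [pool[keys == t] for t in perm_trials]
            )
        else:
            order = rng.permutation(pool)
        n_transfer = _round_half_even(spec.beta * len(pool))
        return np.sort(order[:n_transfer])

    # -- public API -----------------------------------------------------
    def partition(
        self,
        segset: SegmentSet,
        fold_idx: int,
        folds: FoldAssignment | None = None,
    ) -> Partition:
        spec = self.spec
        if folds is None:
            folds = self.folds(segset)
        fold_segments = self._fold_segments(segset, folds, fold_idx)
        test_idx = self._draw_test(segset, fold_segments, fold_idx)
        pool = np.setdiff1d(fold_segments, test_idx)
        non_fold = np.setdiff1d(np.arange(len(segset)), fold_segments)
        if spec.mode == "combined":
            if spec.direction != "forward":
                raise ValueError("combined mode supports forward direction only")
            # restrict training material (not the test set) to the leading
            # rho fraction of every trial
            window_hi = spec.rho * segset.D
            non_fold = _segments_in_window(segset, non_fold, 0.0, window_hi)
            # permute the full pool first so that rho=1 reproduces the
            # subject-independent transfer set exactly
            transfer_order = self._transfer_order(segset, pool, fold_idx)
            restricted = _segments_in_window(
                segset, transfer_order, 0.0, window_hi
            )
            n_transfer = _round_half_even(spec.beta * len(restricted))
            transfer_idx = np.sort(restricted[:n_transfer])
        else:
            transfer_idx = self._draw_transfer(segset, pool, fold_idx)
        train_idx = np.sort(np.concatenate([non_fold, transfer_idx]))
        return Partition(
            fold=fold_idx,
            train_idx=train_idx,
            test_idx=test_idx,
            transfer_idx=transfer_idx,
            R=len(pool) / len(segset),
            spec=replace(spec),
        )

    def _transfer_order(
        self, segset: SegmentSet, pool: np.ndarray, fold_idx: int
    ) -> np.ndarray:
        rng = spawn_rng(self.spec.seed, "transfer", fold_idx)
        if self.spec.transfer_unit == "trial":
            keys = segset.subject[pool] * (segset.video.max() + 1) + (
                segset.video[pool]
            )
            perm_trials = rng.permutation(np.unique(keys))
            return np.concatenate([pool[keys == t] for t in perm_trials])
        return rng.permutation(pool)

    def split(self, segset: SegmentSet) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        folds = self.folds(segset)
        for fold_idx in range(self.spec.k):
            p = self.partition(segset, fold_idx, folds)
            yield p.train_idx, p.test_idx


class TimeBasedSplitter:
    """Within-trial temporal split: test on the tail, train on a window.

    Per trial, the last ``test_tail`` fraction is the test set; the
    training pool spans the remaining prefix of duration
    ``P = D * (1 - test_tail)``. Forward sampling trains on segments fully
    inside ``[0, rho*P)``; backward on ``[P*(1-rho), P)``. Segments
    straddling a boundary are excluded. There is no fold structure.
    """

    def __init__(self, spec: SplitSpec):
        spec.validate()
        if spec.mode != "time_based":
            raise ValueError("TimeBasedSplitter requires mode='time_based'")
        self.spec = spec

    def get_n_splits(self, segset: SegmentSet | None = None) -> int:
        return 1

    def partition(self, segset: SegmentSet) -> Partition:
        spec = self.spec
        D = segset.D
        P = D * (1.0 - spec.test_tail)
        all_idx = np.arange(len(segset))
        test_idx = _segments_in_window(segset, all_idx, P, D)
        pool = _segments_in_window(segset, all_idx, 0.0, P)
        if spec.direction == "forward":
            lo, hi = 0.0, spec.rho * P
        else:
            lo, hi = P * (1.0 - spec.rho), P
        train_idx = _segments_in_window(segset, pool, lo, hi)
        if len(train_idx) == 0:
            raise ValueError(
                f"empty training set: no segment of T={segset.T}s fits in "
                f"the rho={spec.rho} window [{lo:.3g}, {hi:.3g})s"
            )
        return Partition(
            fold=0,
            train_idx=np.sort(train_idx),
            test_idx=np.sort(test_idx),
            transfer_idx=np.array([], dtype=np.int64),
            R=len(pool) / len(segset),
            spec=replace(spec),
        )

    def split(self, segset: SegmentSet) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        p = self.partition(segset)
        yield p.train_idx, p.test_idx


# -- functional wrappers -----------------------------------------------


def subject_independent_split(
    segset: SegmentSet,
    folds: FoldAssignment | None,
    fold_idx: int,
    spec: SplitSpec,
) -> Partition:
    spec = replace(spec, mode="subject_independent")
    return TransferRateSplitter(spec).partition(segset, fold_idx, folds)


def video_independent_split(
    segset: SegmentSet,
    folds: FoldAssignment | None,
    fold_idx: int,
    spec: SplitSpec,
) -> Partition:
    spec = replace(spec, mode="video_independent")
    return TransferRateSplitter(spec).partition(segset, fold_idx, folds)


def time_based_split(segset: SegmentSet, spec: SplitSpec) -> Partition:
    spec = replace(spec, mode="time_based")
    return TimeBasedSplitter(spec).partition(segset)


def combined_split(
    segset: SegmentSet,
    folds: FoldAssignment | None,
    fold_idx: int,
    spec: SplitSpec,
) -> Partition:
    spec = replace(spec, mode="combined")
    return TransferRateSplitter(spec).partition(segset, fold_idx, folds)


def leakage_report(partition: Partition, segset: SegmentSet) -> dict:
    """Audit a partition for the standard leakage channels.

    Reports sizes, the realised transfer fraction, subject/video overlap
    between train and test, the class balance of each side, and the
    minimum temporal gap (seconds) between any train and test segment of
    the same trial (0 means temporally adjacent or overlapping material).
    """
    tr, te = partition.train_idx, partition.test_idx
    train_subjects = set(segset.subject[tr].tolist())
    test_subjects = set(segset.subject[te].tolist())
    train_videos = set(segset.video[tr].tolist())
    test_videos = set(segset.video[te].tolist())
    pool_size = _round_half_even(partition.R * len(segset))
    min_gap = np.inf
    trial_keys = segset.subject.astype(np.int64) * (
        segset.video.max() + 1
    ) + segset.video
    te_by_trial: dict[int, np.ndarray] = {}
    for i in te:
        te_by_trial.setdefault(int(trial_keys[i]), []).append(
            segset.start_s[i]
        )
    for i in tr:
        key = int(trial_keys[i])
        if key not in te_by_trial:
            continue
        s_tr = segset.start_s[i]
        for s_te in te_by_trial[key]:
            if s_te >= s_tr:
                gap = max(0.0, s_te - (s_tr + segset.T))
            else:
                gap = max(0.0, s_tr - (s_te + segset.T))
            min_gap = min(min_gap, gap)
    return {
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
        "n_transfer": int(len(partition.transfer_idx)),
        "realized_beta": (
            len(partition.transfer_idx) / pool_size if pool_size else 0.0
        ),
        "transfer_fraction_of_total": len(partition.transfer_idx)
        / len(segset),
        "subject_overlap": len(train_subjects & test_subjects),
        "video_overlap": len(train_videos & test_videos),
        "train_positive_fraction": float(segset.y[tr].mean())
        if len(tr)
        else float("nan"),
        "test_positive_fraction": float(segset.y[te].mean())
        if len(te)
        else float("nan"),
        "min_temporal_gap_s": float(min_gap),
    }
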