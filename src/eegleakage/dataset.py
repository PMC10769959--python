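"""In-memory dataset container, HDF5 persistence, and the DEAP adapter.

A :class:`Dataset` holds one :class:`Trial` per (subject, video) pair: a
3-second pre-stimulus rest recording, the stimulus-period multichannel
signal, and the self-reported affective ratings (valence / arousal /
dominance, each on a 1-9 scale).

The on-disk container is a single HDF5 file with one group per subject::

    /subjects/<id>/rest      (V, C, 3*f)
    /subjects/<id>/stimulus  (V, C, D*f)
    /subjects/<id>/ratings   (V, 3)
    /subjects/<id>/videos    (V,)

and root attributes ``f`` (Hz), ``C`` (channels), ``D`` (stimulus seconds).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import h5py
import numpy as np

REST_SECONDS = 3
RATING_DIMENSIONS = ("valence", "arousal", "dominance")

# DEAP per-subject preprocessed array layout
DEAP_TRIALS = 40
DEAP_CHANNELS_TOTAL = 40  # 32 EEG + 8 peripheral
DEAP_EEG_CHANNELS = 32
DEAP_SAMPLES = 8064  # 63 s at 128 Hz
DEAP_RATE = 128


class ContainerFormatError(ValueError):
    """The on-disk container is malformed; the message names the field."""


@dataclass
class Trial:
    """One (subject, video) recording.

    Parameters
    ----------
    subject_id, video_id : int
        1-based identifiers.
    rest : ndarray of shape (C, 3*f)
        Pre-stimulus rest-state signal.
    stimulus : ndarray of shape (C, D*f)
        Signal recorded during stimulus presentation.
    ratings : dict
        Maps rating dimension name to a self-reported value in [1, 9].
    """

    subject_id: int
    video_id: int
    rest: np.ndarray
    stimulus: np.ndarray
    ratings: dict[str, float]

    def validate(self, f: int, C: int, D: int) -> None:
        rest = np.asarray(self.rest)
        stim = np.asarray(self.stimulus)
        if rest.shape != (C, REST_SECONDS * f):
            raise ValueError(
                f"trial ({self.subject_id},{self.video_id}): rest shape "
                f"{rest.shape} != ({C}, {REST_SECONDS * f})"
            )
        if stim.shape != (C, D * f):
            raise ValueError(
                f"trial ({self.subject_id},{self.video_id}): stimulus shape "
                f"{stim.shape} != ({C}, {D * f})"
            )
        for name, value in self.ratings.items():
            if not (1.0 <= float(value) <= 9.0):
                raise ValueError(
                    f"trial ({self.subject_id},{self.video_id}): rating "
                    f"{name}={value} outside [1, 9]"
                )


@dataclass
class Dataset:
    """A collection of trials sharing sampling rate, channels and duration.

    Exactly one trial per (subject, video) pair is required.
    """

    trials: list[Trial]
    f: int
    C: int
    D: int
    subject_ids: list[int] = field(default_factory=list)
    video_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subject_ids:
            self.subject_ids = sorted({t.subject_id for t in self.trials})
        if not self.video_ids:
            self.video_ids = sorted({t.video_id for t in self.trials})
        self.trials.sort(key=lambda t: (t.subject_id, t.video_id))

    def validate(self) -> None:
        pairs = [(t.subject_id, t.video_id) for t in self.trials]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (subject, video) pair in dataset")
        expected = {(s, v) for s in self.subject_ids for v in self.video_ids}
        if set(pairs) != expected:
            raise ValueError(
                "dataset must hold exactly one trial per (subject, video) pair"
            )
        for t in self.trials:
            t.validate(self.f, self.C, self.D)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_videos(self) -> int:
        return len(self.video_ids)

    def trial(self, subject_id: int, video_id: int) -> Trial:
        for t in self.trials:
            if t.subject_id == subject_id and t.video_id == video_id:
                return t
        raise KeyError(f"no trial for subject {subject_id}, video {video_id}")


def write_container(dataset: Dataset, path: str | os.PathLike) -> None:
    """Write ``dataset`` to an HDF5 container, atomically replacing ``path``."""
    dataset.validate()
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as h5:
            h5.attrs["format"] = "eegleakage-dataset"
            h5.attrs["f"] = dataset.f
            h5.attrs["C"] = dataset.C
            h5.attrs["D"] = dataset.D
            h5.attrs["rating_dimensions"] = list(RATING_DIMENSIONS)
            subjects = h5.create_group("subjects")
            for sid in dataset.subject_ids:
                trials = [t for t in dataset.trials if t.subject_id == sid]
                grp = subjects.create_group(str(sid))
                grp.create_dataset(
                    "rest", data=np.stack([t.rest for t in trials])
                )
                grp.create_dataset(
                    "stimulus", data=np.stack([t.stimulus for t in trials])
                )
                grp.create_dataset(
                    "ratings",
                    data=np.array(
                        [
                            [t.ratings[d] for d in RATING_DIMENSIONS]
                            for t in trials
                        ]
                    ),
                )
                grp.create_dataset(
                    "videos", data=np.array([t.video_id for t in trials])
                )
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def read_container(path: str | os.PathLike) -> Dataset:
    """Read a container written by :func:`write_container`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ContainerFormatError
        If a required group, dataset or attribute is missing.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    trials: list[Trial] = []
    with h5py.File(path, "r") as h5:
        for attr in ("f", "C", "D"):
            if attr not in h5.attrs:
                raise ContainerFormatError(f"missing root attribute {attr!r}")
        f, C, D = int(h5.attrs["f"]), int(h5.attrs["C"]), int(h5.attrs["D"])
        if "subjects" not in h5:
            raise ContainerFormatError("missing group 'subjects'")
        for sid_str, grp in h5["subjects"].items():
            for name in ("rest", "stimulus", "ratings", "videos"):
                if name not in grp:
                    raise ContainerFormatError(
                        f"subject {sid_str}: missing dataset {name!r}"
                    )
            sid = int(sid_str)
            rest = grp["rest"][...]
            stim = grp["stimulus"][...]
            ratings = grp["ratings"][...]
            videos = grp["videos"][...]
            for i, vid in enumerate(videos):
                trials.append(
                    Trial(
                        subject_id=sid,
                        video_id=int(vid),
                        rest=rest[i],
                        stimulus=stim[i],
                        ratings={
                            d: float(ratings[i, j])
                            for j, d in enumerate(RATING_DIMENSIONS)
                        },
                    )
                )
    ds = Dataset(trials=trials, f=f, C=C, D=D)
    ds.validate()
    return ds


def adapt_deap(
    trial_array: np.ndarray, rating_array: np.ndarray, subject_id: int
) -> list[Trial]:
    """Adapt one subject's DEAP preprocessed arrays into trials.

    DEAP ships, per subject, a (40, 40, 8064) array — 40 trials, 32 EEG
    channels plus 8 peripheral channels, 63 s at 128 Hz — and a (40, 4)
    rating array in (valence, arousal, dominance, liking) column order.
    The 8 peripheral channels and the liking rating are discarded; the
    first 3 s (384 samples) become the rest-state prefix and the remaining
    60 s (7680 samples) the stimulus signal.
    """
    trial_array = np.asarray(trial_array)
    rating_array = np.asarray(rating_array)
    if trial_array.shape != (DEAP_TRIALS, DEAP_CHANNELS_TOTAL, DEAP_SAMPLES):
        raise ValueError(
            "DEAP trial array must have shape "
            f"({DEAP_TRIALS}, {DEAP_CHANNELS_TOTAL}, {DEAP_SAMPLES}), "
            f"got {trial_array.shape}"
        )
    if rating_array.shape != (DEAP_TRIALS, 4):
        raise ValueError(
            f"DEAP rating array must have shape ({DEAP_TRIALS}, 4), "
            f"got {rating_array.shape}"
        )
    rest_len = REST_SECONDS * DEAP_RATE  # 384
    trials = []
    for v in range(DEAP_TRIALS):
        eeg = trial_array[v, :DEAP_EEG_CHANNELS, :]
        trial = Trial(
            subject_id=subject_id,
            video_id=v + 1,
            rest=eeg[:, :rest_len],
            stimulus=eeg[:, rest_len:],
            ratings={
                d: float(rating_array[v, j])
                for j, d in enumerate(RATING_DIMENSIONS)
            },
        )
        trial.validate(DEAP_RATE, DEAP_EEG_CHANNELS, 60)
        trials.append(trial)
    return trials
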