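"""Rest-state baseline correction, scaling, label binarisation, segmentation.

The preprocessing chain mirrors the standard segment-level pipeline for
affective EEG: the per-channel mean of the 3-s pre-stimulus rest recording
is subtracted channel-wise from the stimulus signal, each channel is then
scaled to unit maximum absolute value over the whole trial, the continuous
1-9 rating is binarised (<= 5 negative, > 5 positive), and the trial is cut
into fixed-duration segments that inherit the trial label and carry full
provenance (subject, video, start time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .dataset import Dataset, Trial, REST_SECONDS

logger = logging.getLogger(__name__)

NEGATIVE, POSITIVE = 0, 1
CLASS_NAMES = {NEGATIVE: "negative", POSITIVE: "positive"}


@dataclass
class Segment:
    """A fixed-duration slice of one trial's preprocessed signal."""

    subject_id: int
    video_id: int
    start_s: float  # start within the stimulus, seconds, [start, start+T)
    T: float  # duration, seconds
    data: np.ndarray  # (C, L) with L = f*T
    label: int  # NEGATIVE or POSITIVE


class SegmentSet:
    """Ordered segment collection with provenance and index maps.

    Segments are stored column-wise in dense arrays for cheap fancy
    indexing by the partition machinery:

    Attributes
    ----------
    X : ndarray of shape (n, C, L)
    y : ndarray of shape (n,) — 0 negative, 1 positive
    subject, video : int arrays of shape (n,)
    start_s : float array of shape (n,)
    T, overlap, label_dimension, f, D : preprocessing provenance
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        subject: np.ndarray,
        video: np.ndarray,
        start_s: np.ndarray,
        *,
        T: float,
        overlap: float,
        label_dimension: str,
        f: int,
        D: int,
    ):
        self.X = np.asarray(X, dtype=np.float32)
        self.y = np.asarray(y, dtype=np.int64)
        self.subject = np.asarray(subject, dtype=np.int64)
        self.video = np.asarray(video, dtype=np.int64)
        self.start_s = np.asarray(start_s, dtype=np.float64)
        self.T = float(T)
        self.overlap = float(overlap)
        self.label_dimension = label_dimension
        self.f = int(f)
        self.D = int(D)
        n = len(self.X)
        for name in ("y", "subject", "video", "start_s"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of segments")
        self.by_subject = {
            int(s): np.flatnonzero(self.subject == s)
            for s in np.unique(self.subject)
        }
        self.by_video = {
            int(v): np.flatnonzero(self.video == v)
            for v in np.unique(self.video)
        }
        self.by_trial = {
            (int(s), int(v)): np.flatnonzero(
                (self.subject == s) & (self.video == v)
            )
            for s in np.unique(self.subject)
            for v in np.unique(self.video)
        }

    def __len__(self) -> int:
        return len(self.X)

    @property
    def C(self) -> int:
        return self.X.shape[1]

    @property
    def L(self) -> int:
        return self.X.shape[2]

    def segments(self) -> list[Segment]:
        """Materialise the row-wise :class:`Segment` view."""
        return [
            Segment(
                subject_id=int(self.subject[i]),
                video_id=int(self.video[i]),
                start_s=float(self.start_s[i]),
                T=self.T,
                data=self.X[i],
                label=int(self.y[i]),
            )
            for i in range(len(self))
        ]


def rest_mean(trial: Trial) -> np.ndarray:
    """Per-channel mean of the 3-s rest prefix.

    Computed as the grand mean over all rest samples, which equals the mean
    of the three 1-s segment means because the segments have equal length.
    """
    rest = np.asarray(trial.rest)
    C = np.asarray(trial.stimulus).shape[0]
    if rest.ndim != 2 or rest.shape[0] != C or rest.shape[1] % REST_SECONDS:
        raise ValueError(
            f"rest prefix must be (C, {REST_SECONDS}*f), got {rest.shape}"
        )
    return rest.mean(axis=1)


def baseline_subtract(trial: Trial) -> Trial:
    """Subtract the rest-state channel means from the stimulus signal."""
    mu = rest_mean(trial)
    return replace(trial, stimulus=np.asarray(trial.stimulus) - mu[:, None])


def scale_maxabs(trial: Trial) -> Trial:
    """Scale each stimulus channel to unit maximum absolute value.

    An all-zero channel cannot be scaled; it is left unchanged and a
    warning is logged.
    """
    stim = np.asarray(trial.stimulus, dtype=float)
    peaks = np.abs(stim).max(axis=1)
    zero = peaks == 0.0
    if zero.any():
        logger.warning(
            "trial (%d,%d): channel(s) %s are all-zero; left unscaled",
            trial.subject_id,
            trial.video_id,
            np.flatnonzero(zero).tolist(),
        )
    safe = np.where(zero, 1.0, peaks)
    return replace(trial, stimulus=stim / safe[:, None])


def binarize_label(rating: float) -> int:
    """Binarise a 1-9 rating: <= 5 negative, > 5 positive."""
    rating = float(rating)
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating {rating} outside [1, 9]")
    return POSITIVE if rating > 5.0 else NEGATIVE


def segment_starts(D: float, T: float, overlap: float, f: int) -> np.ndarray:
    """Start times (seconds) of the segment grid; validates the geometry."""
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if T > D:
        raise ValueError(f"segment duration T={T} exceeds trial D={D}")
    L = T * f
    if abs(L - round(L)) > 1e-9:
        raise ValueError(f"T={T}s does not give an integer sample count at f={f}")
    stride = T * (1.0 - overlap)
    stride_samples = stride * f
    if abs(stride_samples - round(stride_samples)) > 1e-9:
        raise ValueError(
            f"stride T*(1-overlap)={stride}s is not an integer sample count "
            f"at f={f} (T={T}, overlap={overlap})"
        )
    n = int(np.floor((D - T) / stride + 1e-9)) + 1
    return np.arange(n) * stride


def segment_trial(
    trial: Trial,
    T: float,
    overlap: float = 0.0,
    *,
    f: int,
    label_dimension: str = "valence",
) -> list[Segment]:
    """Cut a preprocessed trial into labelled fixed-duration segments.

    Segments start at 0, stride, 2*stride, ... with stride = T*(1-overlap);
    an incomplete trailing window is dropped. Every segment inherits the
    binarised label of its parent trial.
    """
    stim = np.asarray(trial.stimulus)
    D = stim.shape[1] / f
    starts = segment_starts(D, T, overlap, f)
    L = int(round(T * f))
    label = binarize_label(trial.ratings[label_dimension])
    out = []
    for s0 in starts:
        i0 = int(round(s0 * f))
        out.append(
            Segment(
                subject_id=trial.subject_id,
                video_id=trial.video_id,
                start_s=float(s0),
                T=float(T),
                data=stim[:, i0 : i0 + L],
                label=label,
            )
        )
    return out


def prepare(
    dataset: Dataset,
    T: float,
    overlap: float = 0.0,
    label_dimension: str = "valence",
    *,
    scale_scope: str = "trial",
) -> SegmentSet:
    """Full preprocessing chain over a dataset.

    Applies, per trial, baseline subtraction then max-abs scaling then
    segmentation, and assembles the labelled sample table. ``scale_scope``
    selects whether channels are scaled over the whole trial (default; all
    segments of a trial are consistent slices of one signal) or per segment.
    """
    if scale_scope not in ("trial", "segment"):
        raise ValueError("scale_scope must be 'trial' or 'segment'")
    data, labels, subjects, videos, starts = [], [], [], [], []
    for trial in dataset.trials:
        if label_dimension not in trial.ratings:
            raise KeyError(
                f"trial ({trial.subject_id},{trial.video_id}) lacks rating "
                f"dimension {label_dimension!r}"
            )
        processed = baseline_subtract(trial)
        if scale_scope == "trial":
            processed = scale_maxabs(processed)
        segs = segment_trial(
            processed,
            T,
            overlap,
            f=dataset.f,
            label_dimension=label_dimension,
        )
        for seg in segs:
            d = seg.data
            if scale_scope == "segment":
                peaks = np.abs(d).max(axis=1)
                d = d / np.where(peaks == 0.0, 1.0, peaks)[:, None]
            data.append(d)
            labels.append(seg.label)
            subjects.append(seg.subject_id)
            videos.append(seg.video_id)
            starts.append(seg.start_s)
    return SegmentSet(
        np.stack(data),
        np.array(labels),
        np.array(subjects),
        np.array(videos),
        np.array(starts),
        T=T,
        overlap=overlap,
        label_dimension=label_dimension,
        f=dataset.f,
        D=dataset.D,
    )
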