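"""Synthetic EEG generator with controllable leakage structure.

Real affective EEG is dominated by who is being recorded rather than by
what they feel: inter-subject variability is large, neighbouring signal
segments are strongly correlated, and the emotion-related component tends
to build up over the course of a stimulus. The generator reproduces those
three properties — and only those — with an additive latent model, per
channel ``c`` and sample ``t`` of the stimulus period of trial ``(s, v)``::

    x(c, t) = b_s(c)                      subject-specific rest baseline
            + u_s(c) * g_sv(t)            subject idiosyncrasy
            + w_v(c) * h_v(t)             video signature
            + y_sv * d_s(c) * a(t)        class-discriminative component
            + AR(1) noise                 temporal autocorrelation

``y_sv ∈ {-1, +1}`` is the latent affective class of the trial; ``d_s`` is
a unit spatial direction, drawn independently per subject when
``subject_specific_classes`` is set (so the class code does not transfer
across subjects — the mechanism that makes cross-subject decoding hard);
``a(t)`` ramps linearly from 0 to ``class_amp`` over the first ``ramp``
fraction of the trial, then stays constant, so late segments are more
discriminative. The rest prefix contains only baseline plus noise.
Carriers are smoothed (moving-average) noise, not sinusoids, to avoid
trivially learnable periodicity; the subject carrier ``g_sv`` is drawn
fresh per trial (the subject's fixed trait is the spatial pattern
``u_s``), while the video carrier ``h_v`` is stimulus-locked and shared
across subjects. No attempt is made at
physiological spectra or artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ._seeds import spawn_rng
from .dataset import Dataset, Trial, REST_SECONDS, RATING_DIMENSIONS

__all__ = ["GeneratorConfig", "ar1_path", "sample_rating", "generate"]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic EEG generator.

    Amplitudes are in arbitrary signal units; the downstream per-channel
    max-abs scaling makes only their ratios matter. Defaults are calibrated
    so that (i) the class component is reliably decodable within a subject
    but carries no information across subjects when
    ``subject_specific_classes`` is set, and (ii) the noise correlation
    time (phi=0.995 per sample, ~1.6 s at 128 Hz; stationary sd
    sigma_noise / sqrt(1 - phi^2) ~= 1) is comparable to the longest
    segment durations in use, so longer segments cannot average the noise
    away and neighbouring segments are genuinely similar.
    """

    S: int = 8  # subjects
    V: int = 10  # videos
    C: int = 8  # channels
    f: int = 128  # Hz
    D: int = 60  # stimulus seconds
    sigma_subject: float = 1.0  # amplitude of the subject idiosyncrasy
    sigma_video: float = 0.5  # amplitude of the video signature
    class_amp: float = 5.0  # peak amplitude of the class component
    ramp: float = 0.5  # fraction of the trial over which a(t) ramps up
    phi: float = 0.995  # AR(1) coefficient of the noise
    sigma_noise: float = 0.1  # AR(1) innovation scale
    subject_specific_classes: bool = True
    balanced_classes: bool = False  # exactly half positive per subject
    rest_offset_scale: float = 0.5  # per-(subject, channel) rest baseline
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "sigma_subject",
            "sigma_video",
            "class_amp",
            "sigma_noise",
            "rest_offset_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")
        if not 0.0 <= self.ramp <= 1.0:
            raise ValueError("ramp must lie in [0, 1]")
        for name in ("S", "V", "C", "f", "D"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def ar1_path(
    n: int, phi: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) path: x_t = phi * x_{t-1} + eps_t.

    The first sample is drawn from the stationary distribution
    N(0, sigma^2 / (1 - phi^2)), so the whole path is stationary with
    lag-1 autocorrelation ``phi``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= phi < 1.0:
        raise ValueError("phi must lie in [0, 1)")
    if sigma == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sigma, size=n)
    eps[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi * phi))
    if phi == 0.0:
        return eps
    # scipy.signal.lfilter would do; the explicit recursion keeps the
    # dependency surface minimal and is fast enough at these sizes.
    x = np.empty(n)
    acc = eps[0]
    x[0] = acc
    for t in range(1, n):
        acc = phi * acc + eps[t]
        x[t] = acc
    return x


def _ar1_matrix(
    shape: tuple[int, int], phi: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent AR(1) paths along the last axis, vectorised over rows."""
    rows, n = shape
    if sigma == 0.0:
        return np.zeros(shape)
    eps = rng.normal(0.0, sigma, size=shape)
    eps[:, 0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi * phi), size=rows)
    if phi == 0.0:
        return eps
    x = np.empty(shape)
    acc = eps[:, 0].copy()
    x[:, 0] = acc
    for t in range(1, n):
        acc = phi * acc + eps[:, t]
        x[:, t] = acc
    return x


def sample_rating(y: int, rng: np.random.Generator) -> float:
    """Draw a 1-9 rating consistent with latent class ``y``.

    Negative trials (y = -1) rate uniformly on [1, 5]; positive trials
    (y = +1) on (5, 9]. Binarising the rating at the standard threshold
    (<= 5 negative) always recovers ``y``.
    """
    if y == -1:
        return float(rng.uniform(1.0, 5.0))
    if y == 1:
        # open at 5: nextafter keeps the draw strictly above the threshold
        return float(rng.uniform(np.nextafter(5.0, 9.0), 9.0))
    raise ValueError("y must be -1 or +1")


def _smooth_carrier(
    n: int, window: int, rng: np.random.Generator
) -> np.ndarray:
    """Moving-average-smoothed white noise, normalised to unit variance."""
    raw = rng.normal(size=n + window - 1)
    kernel = np.ones(window) / window
    carrier = np.convolve(raw, kernel, mode="valid")
    sd = carrier.std()
    if sd > 0:
        carrier /= sd
    return carrier


def _unit_vector(C: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=C)
    return v / np.linalg.norm(v)


def generate(config: GeneratorConfig) -> Dataset:
    """Generate one trial per (subject, video) pair under ``config``.

    Fully reproducible: the same config (including seed) yields a
    bit-identical dataset.
    """
    config.validate()
    S, V, C, f, D = config.S, config.V, config.C, config.f, config.D
    n_stim = D * f
    n_rest = REST_SECONDS * f

    rng = spawn_rng(config.seed, "generate")
    # Smoothing window ~0.5 s: slow relative to 1-4 s segments.
    window = max(2, f // 2)

    baselines = rng.normal(0.0, config.rest_offset_scale, size=(S, C))
    subject_dirs = np.stack([_unit_vector(C, rng) for _ in range(S)])
    video_dirs = np.stack([_unit_vector(C, rng) for _ in range(V)])
    # Subject idiosyncrasy: a fixed spatial pattern per subject, but a
    # fresh temporal carrier per trial — a subject is recognisable by
    # *where* their activity lives, not by an identical time course
    # repeated in every recording (intra-subject variability). Video
    # signatures, by contrast, are stimulus-locked: one carrier per
    # video, repeated across subjects.
    subject_carriers = {
        (si, vi): _smooth_carrier(n_stim, window, rng)
        for si in range(S)
        for vi in range(V)
    }
    video_carriers = np.stack(
        [_smooth_carrier(n_stim, window, rng) for _ in range(V)]
    )
    shared_class_dir = _unit_vector(C, rng)
    if config.subject_specific_classes:
        # Mutually orthogonal per-subject directions (when they fit in C
        # dimensions): a class code learned on one subject then carries
        # exactly zero signal about any other subject's classes, the
        # cleanest form of subject-specific structure. With more subjects
        # than channels, orthogonality is impossible and independent
        # random directions are used instead.
        if S <= C:
            gauss = rng.normal(size=(C, S))
            q, _ = np.linalg.qr(gauss)
            class_dirs = q.T[:S]
        else:
            class_dirs = np.stack([_unit_vector(C, rng) for _ in range(S)])
    else:
        class_dirs = np.tile(shared_class_dir, (S, 1))

    # a(t): linear ramp to class_amp over the first `ramp` fraction
    t_frac = np.arange(n_stim) / n_stim
    if config.ramp > 0:
        profile = np.minimum(t_frac / config.ramp, 1.0)
    else:
        profile = np.ones(n_stim)
    profile = config.class_amp * profile

    if config.balanced_classes:
        # Exactly V//2 positive trials per subject (one extra at random
        # when V is odd). Removes the finite-population class-imbalance
        # artifact of small trial tables: with i.i.d. fair coins, the
        # training majority anti-correlates with the held-out fold's
        # balance, biasing prior-sensitive classifiers measurably below
        # chance at desk scale (a negligible effect at full scale).
        classes = np.empty((S, V), dtype=int)
        for si in range(S):
            ys = np.array([1] * (V // 2) + [-1] * (V // 2))
            if V % 2:
                ys = np.append(ys, rng.choice([-1, 1]))
            classes[si] = rng.permutation(ys)
    else:
        classes = np.where(rng.random(size=(S, V)) < 0.5, 1, -1)

    trials = []
    for si in range(S):
        for vi in range(V):
            y = int(classes[si, vi])
            stim = (
                baselines[si][:, None]
                + config.sigma_subject
                * np.outer(subject_dirs[si], subject_carriers[si, vi])
                + config.sigma_video
                * np.outer(video_dirs[vi], video_carriers[vi])
                + y * np.outer(class_dirs[si], profile)
            )
            stim = stim + _ar1_matrix(
                (C, n_stim), config.phi, config.sigma_noise, rng
            )
            rest = baselines[si][:, None] + _ar1_matrix(
                (C, n_rest), config.phi, config.sigma_noise, rng
            )
            valence = sample_rating(y, rng)
            # Other dimensions are drawn independently of the class so that
            # only valence carries the generated structure by default.
            others = {
                d: float(rng.uniform(1.0, 9.0))
                for d in RATING_DIMENSIONS
                if d != "valence"
            }
            trials.append(
                Trial(
                    subject_id=si + 1,
                    video_id=vi + 1,
                    rest=rest,
                    stimulus=stim,
                    ratings={"valence": valence, **others},
                )
            )
    ds = Dataset(trials=trials, f=f, C=C, D=D)
    ds.validate()
    return ds
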