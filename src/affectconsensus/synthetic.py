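"""Synthetic annotation, clip-rating and physiology generators.

The generators emulate the statistical structure the pipeline assumes: a
smooth shared latent affect trajectory per film x item, rater observations
that are affine transforms of the latent plus independent Gaussian noise
(clipped to the 0-100 display scale), contaminated raters of three kinds
(constant, extreme-outlier, deviant), sparse clip-sampled ratings covering
roughly a fifth of each film, and quasi-periodic cardiac/respiratory traces
with known event times.

The latent process is Gaussian-kernel-smoothed white noise. For kernel SD
``s`` (in samples) the lag-``k`` autocorrelation has the closed form
``exp(-k^2 / (4 s^2))``, which the tests exploit; at the default 5 s
smoothing the lag-1 autocorrelation is ~0.990, i.e. slow dynamics relative
to the 1 Hz sampling.

Pairwise agreement between two raters sharing a unit-variance latent with
independent noise of SD ``sigma_n`` follows the attenuation law
``r = 1 / (1 + sigma_n^2)``; :func:`choose_noise_for_agreement` inverts it
so simulations can be dialled to a target mean agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidClipError, InvalidParameterError
from .types import (
    SCALE_MAX,
    SCALE_MID,
    SCALE_MIN,
    AnnotationSeries,
    ClipRatingSet,
    LatentSignal,
    PhysioTrace,
)

CONTAMINATION_MODES = ("none", "constant", "outlier", "deviant")

#: Credit-free durations (s) of the 14 short films with reliable consensus
#: annotations; the default film set for whole-study simulations.
FILM_DURATIONS_S: dict[str, int] = {
    "AfterTheRain": 496,
    "BetweenViewings": 808,
    "BigBuckBunny": 490,
    "Chatter": 405,
    "FirstBite": 599,
    "LessonLearned": 667,
    "Payload": 1008,
    "Sintel": 722,
    "Spaceman": 805,
    "Superhero": 1028,
    "TearsOfSteel": 588,
    "TheSecretNumber": 784,
    "ToClaireFromSonny": 402,
    "YouAgain": 798,
}


@dataclass
class RaterModel:
    """Generative model of one rater: affine response plus noise.

    gain scales z-units of the latent onto the 0-100 display scale;
    bias shifts the rater's personal midpoint; noise_sd is in latent
    (z) units. Exactly one contamination mode applies.
    """

    rater_id: str
    gain: float = 10.0
    bias: float = 0.0
    noise_sd: float = 0.0
    contamination: str = "none"

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise InvalidParameterError("gain must be positive")
        if not (np.isfinite(self.noise_sd) and self.noise_sd >= 0):
            raise InvalidParameterError("noise_sd must be finite and >= 0")
        if self.contamination not in CONTAMINATION_MODES:
            raise InvalidParameterError(
                f"contamination must be one of {CONTAMINATION_MODES}"
            )


@dataclass
class SimulationConfig:
    """Study-design parameters for a full synthetic annotation dataset.

    Defaults mirror the annotation-study design: four raters per
    film x item, six items per rater list, a 5 s latent smoothing scale
    and a target mean pairwise agreement of 0.39.
    """

    n_raters_per_combo: int = 4
    items_per_rater: int = 6
    films: dict[str, int] = field(default_factory=lambda: dict(FILM_DURATIONS_S))
    items: tuple[str, ...] = ("item-01",)
    smoothing_sd_s: float = 5.0
    target_agreement: float = 0.39
    contamination_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters_per_combo < 3:
            raise InvalidParameterError("need at least 3 raters per combo")
        if not 0 < self.target_agreement < 1:
            raise InvalidParameterError("target_agreement must be in (0, 1)")
        rates = list(self.contamination_rates.values())
        if any(not 0 <= p <= 1 for p in rates) or sum(rates) > 1 + 1e-12:
            raise InvalidParameterError(
                "contamination rates must lie in [0,1] and sum to at most 1"
            )
        for mode in self.contamination_rates:
            if mode not in CONTAMINATION_MODES[1:]:
                raise InvalidParameterError(f"unknown contamination mode {mode!r}")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise InvalidParameterError("cannot standardize a constant sequence")
    return (x - x.mean()) / sd


def generate_latent(
    duration_s: int,
    smoothing_sd_s: float = 5.0,
    seed: int | np.random.Generator = 0,
    film_id: str = "film",
    item_id: str = "item",
) -> LatentSignal:
    """Smooth standardized latent trajectory: Gaussian-filtered white noise.

    Wrap-around filtering keeps the marginal variance uniform along the
    series, so the closed-form autocorrelation holds away from edges too.
    """
    if duration_s < 30:
        raise InvalidParameterError("duration_s must be at least 30")
    if smoothing_sd_s <= 0:
        raise InvalidParameterError("smoothing_sd_s must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    white = rng.standard_normal(int(duration_s))
    smooth = gaussian_filter1d(white, sigma=smoothing_sd_s, mode="wrap")
    return LatentSignal(
        film_id=film_id, item_id=item_id, values=_standardize(smooth), duration_s=int(duration_s)
    )


def choose_noise_for_agreement(target_agreement: float, signal_sd: float = 1.0) -> float:
    """Noise SD giving expected pairwise Pearson r == ``target_agreement``.

    Inverts the attenuation law r = sigma_s^2 / (sigma_s^2 + sigma_n^2).
    """
    if not 0 < target_agreement < 1:
        raise InvalidParameterError("target_agreement must lie strictly in (0, 1)")
    return signal_sd * math.sqrt(1.0 / target_agreement - 1.0)


def simulate_rater_series(
    latent: LatentSignal,
    rater: RaterModel,
    seed: int | np.random.Generator = 0,
    n_outliers: int = 1,
) -> AnnotationSeries:
    """One rater's raw 0-100 trace for the latent's film x item.

    Clean observation: clip(50 + bias + gain * (latent + eps), 0, 100) with
    eps iid N(0, noise_sd^2). Contamination overrides:

    - ``constant``: every sample equals the rater's midpoint.
    - ``outlier``: the series is generated at a deliberately small gain (a
      low-amplitude rater, SD of a few display units) and ``n_outliers``
      samples are slammed to the far scale extreme. The excursion is then
      tens of within-series SDs, so it exceeds |z| = 15 after within-rater
      normalisation despite the 0-100 clip; a single spike by default,
      since m spikes in N samples cap the attainable |z| near sqrt(N/m).
    - ``deviant``: the shared latent is replaced by an independent draw of
      the same smoothness, so the rater tracks a private signal.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = np.asarray(latent.values, dtype=float)

    if rater.contamination == "constant":
        const = float(np.clip(SCALE_MID + rater.bias, SCALE_MIN, SCALE_MAX))
        return AnnotationSeries(rater.rater_id, latent.film_id, latent.item_id,
                                np.full(values.size, const))

    if rater.contamination == "deviant":
        private = generate_latent(
            latent.duration_s, seed=rng, film_id=latent.film_id, item_id=latent.item_id
        )
        values = private.values

    gain = rater.gain
    if rater.contamination == "outlier":
        # Low-amplitude rater: leaves head-room on the display scale for
        # spikes of >15 within-series SDs.
        gain = min(gain, 1.0)

    eps = rng.normal(0.0, rater.noise_sd, size=values.size)
    obs = SCALE_MID + rater.bias + gain * (values + eps)

    if rater.contamination == "outlier":
        idx = rng.choice(values.size, size=min(n_outliers, values.size), replace=False)
        # Far scale extreme maximises the excursion relative to the mean.
        obs[idx] = np.where(obs.mean() > SCALE_MID, SCALE_MIN, SCALE_MAX)

    return AnnotationSeries(
        rater.rater_id, latent.film_id, latent.item_id,
        np.clip(obs, SCALE_MIN, SCALE_MAX),
    )


def generate_clip_plan(
    duration_s: float,
    n_clips: int | None = None,
    mean_clip_s: float = 7.0,
    clip_jitter_s: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float]]:
    """Non-overlapping clip windows placed uniformly over the film.

    Clip durations are uniform on mean +/- jitter; the remaining free time
    is split into random gaps, so placement carries no positional bias.
    By default the clip count scales with film length at a density of
    ~21 clips per 11.5-minute film (mean duration 7 s), which keeps the
    covered fraction around a fifth of the film for realistic durations.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_clips is None:
        n_clips = max(int(round(21.0 * duration_s / 686.0)), 2)
    if n_clips < 1:
        raise InvalidParameterError("n_clips must be >= 1")
    durations = rng.uniform(mean_clip_s - clip_jitter_s, mean_clip_s + clip_jitter_s, n_clips)
    durations = np.maximum(durations, 1.0)
    total = durations.sum()
    if total >= duration_s:
        raise InvalidClipError(
            f"clip plan needs {total:.1f} s but film lasts only {duration_s} s"
        )
    # n_clips + 1 gaps (film start, between clips, film end), Dirichlet-uniform.
    gaps = rng.dirichlet(np.ones(n_clips + 1)) * (duration_s - total)
    clips: list[tuple[float, float]] = []
    t = 0.0
    for d, g in zip(durations, gaps[:-1]):
        t += g
        clips.append((t, t + d))
        t += d
    return clips


def simulate_clip_ratings(
    latent: LatentSignal,
    clip_plan: list[tuple[float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sub-01",
    gain: float = 10.0,
    bias: float = 0.0,
) -> ClipRatingSet:
    """Sparse clip ratings: per-clip latent mean plus noise on the 0-100 scale.

    Each rating is the mean of the latent over the clip window plus
    N(0, noise_sd^2) noise, mapped through the same affine display
    transform as the continuous annotations.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if clip_plan is None:
        clip_plan = generate_clip_plan(latent.duration_s, seed=rng)
    clips: list[tuple[float, float, float]] = []
    last_off = -np.inf
    for onset, offset in clip_plan:
        if onset < 0 or offset > latent.duration_s:
            raise InvalidClipError(
                f"clip [{onset}, {offset}] outside film of {latent.duration_s} s"
            )
        if onset < last_off:
            raise InvalidClipError("clip plan contains overlapping clips")
        last_off = offset
        lo, hi = int(math.floor(onset)), max(int(math.ceil(offset)), int(math.floor(onset)) + 1)
        clip_mean = float(latent.values[lo:hi].mean())
        value = SCALE_MID + bias + gain * (clip_mean + rng.normal(0.0, noise_sd))
        clips.append((float(onset), float(offset), float(np.clip(value, SCALE_MIN, SCALE_MAX))))
    return ClipRatingSet(
        subject_id=subject_id,
        film_id=latent.film_id,
        item_id=latent.item_id,
        clips=clips,
        film_duration_s=float(latent.duration_s),
    )


def simulate_physio_trace(
    kind: str,
    duration_s: float,
    rate_hz: float = 1000.0,
    period_s: float | None = None,
    jitter_sd_s: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[PhysioTrace, np.ndarray]:
    """Quasi-periodic physiological trace with ground-truth event times.

    ``cardiac`` builds a pulse-wave train (narrow Gaussian systolic peak per
    beat); ``respiration`` a phase-modulated sinusoid whose cycle onsets are
    the events. Returns (trace, event_times_s).
    """
    if kind not in ("cardiac", "respiration"):
        raise InvalidParameterError(f"kind must be 'cardiac' or 'respiration', got {kind!r}")
    if duration_s <= 0 or rate_hz <= 0:
        raise InvalidParameterError("duration_s and rate_hz must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if period_s is None:
        period_s = 1.0 if kind == "cardiac" else 4.0

    # Event (beat / breath-onset) times with jittered inter-event intervals.
    events = []
    t = period_s / 2.0
    while t < duration_s - period_s / 4.0:
        events.append(t)
        t += max(period_s + rng.normal(0.0, jitter_sd_s), period_s / 4.0)
    events_arr = np.asarray(events)

    n = int(round(duration_s * rate_hz))
    times = np.arange(n) / rate_hz
    if kind == "cardiac":
        width = period_s / 10.0
        signal = np.zeros(n)
        for ev in events_arr:
            lo = max(int((ev - 4 * width) * rate_hz), 0)
            hi = min(int((ev + 4 * width) * rate_hz) + 1, n)
            signal[lo:hi] += np.exp(-((times[lo:hi] - ev) ** 2) / (2 * width**2))
    else:
        # Piecewise phase: one full cycle between consecutive events.
        anchors = np.concatenate(([0.0], events_arr, [duration_s]))
        phase = np.interp(times, anchors, np.arange(anchors.size) * 2 * np.pi)
        signal = np.sin(phase)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    trace = PhysioTrace(modality=kind, sampling_rate=rate_hz, values=signal)
    return trace, events_arr


@dataclass
class SimulatedDataset:
    """Output of :func:`simulate_annotation_dataset`."""

    series: list[AnnotationSeries]
    latents: dict[tuple[str, str], LatentSignal]
    contamination: dict[tuple[str, str, str], str]
    config: SimulationConfig


def simulate_annotation_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full synthetic annotation study: latents, raters, contamination.

    For every film x item a shared latent is drawn; ``n_raters_per_combo``
    raters observe it with noise set by ``target_agreement``. Gain, bias
    and contamination are rater characteristics, held fixed across the
    rater's films; contaminated keys are returned per film x item as
    ground truth for screen sensitivity/specificity checks.
    """
    rng = np.random.default_rng(config.seed)
    noise_sd = choose_noise_for_agreement(config.target_agreement)
    modes = list(config.contamination_rates)
    probs = [config.contamination_rates[m] for m in modes]

    series: list[AnnotationSeries] = []
    latents: dict[tuple[str, str], LatentSignal] = {}
    truth: dict[tuple[str, str, str], str] = {}
    for item in config.items:
        for film, dur in config.films.items():
            latents[(film, item)] = generate_latent(
                dur, config.smoothing_sd_s, seed=rng, film_id=film, item_id=item
            )
        # Draw contamination iid per rater, then cap at one contaminated
        # rater per item group: the mean-r exclusion rule is identifiable
        # only against a clean majority sharing the latent.
        drawn = []
        for _ in range(config.n_raters_per_combo):
            mode = "none"
            if modes:
                u = rng.random()
                acc = 0.0
                for m, p in zip(modes, probs):
                    acc += p
                    if u < acc:
                        mode = m
                        break
            drawn.append(mode)
        contaminated = [i for i, m in enumerate(drawn) if m != "none"]
        if len(contaminated) > 1:
            keep = contaminated[int(rng.integers(len(contaminated)))]
            drawn = [m if i == keep else "none" for i, m in enumerate(drawn)]
        film_ids = list(config.films)
        for k in range(config.n_raters_per_combo):
            rater_id = f"r{k + 1:02d}-{item}"
            mode = drawn[k]
            gain = float(rng.uniform(8.0, 14.0))
            bias = float(rng.uniform(-8.0, 8.0))
            # An outlier rater is a low-amplitude rater with a single glitch
            # in one film: pooling all their films then leaves the spike as
            # 1 sample in N, the regime where |z| > 15 is reachable.
            spike_film = film_ids[int(rng.integers(len(film_ids)))] if mode == "outlier" else None
            if mode == "outlier":
                gain = min(gain, 1.0)
            for film in film_ids:
                if mode == "outlier":
                    film_mode = "outlier" if film == spike_film else "none"
                else:
                    film_mode = mode
                rater = RaterModel(
                    rater_id=rater_id, gain=gain, bias=bias,
                    noise_sd=noise_sd, contamination=film_mode,
                )
                series.append(simulate_rater_series(latents[(film, item)], rater, seed=rng))
                if mode == "outlier":
                    if film == spike_film:
                        truth[(rater_id, film, item)] = mode
                elif mode != "none":
                    truth[(rater_id, film, item)] = mode
    return SimulatedDataset(series=series, latents=latents, contamination=truth, config=config)
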