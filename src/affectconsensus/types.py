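"""Core data containers shared across the pipeline.

Continuous annotations are 1 Hz traces on a 0-100 display scale, one per
rater x film x item. Downstream stages operate on z-scored versions of the
same container; the ``state`` field tracks which representation a series
holds so that stage contracts can be enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AlignmentError, InvalidClipError, InvalidParameterError

RAW = "raw"
ZSCORED = "zscored"

#: Annotation sampling rate in Hz, fixed by the acquisition software.
ANNOTATION_RATE_HZ = 1.0

#: Display-scale bounds of the rating slider.
SCALE_MIN, SCALE_MAX = 0.0, 100.0
SCALE_MID = 50.0


@dataclass
class AnnotationSeries:
    """One rater's 1 Hz annotation trace for one film x item.

    ``values`` uses NaN for missing samples; ``missing_mask`` is derived.
    Raw series live on the 0-100 display scale, z-scored series in z-units
    after pooling the rater's films for the item.
    """

    rater_id: str
    film_id: str
    item_id: str
    values: np.ndarray
    state: str = RAW
    sampling_rate: float = ANNOTATION_RATE_HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidParameterError("annotation values must be 1-D")
        if self.state not in (RAW, ZSCORED):
            raise InvalidParameterError(f"unknown state {self.state!r}")
        if self.state == RAW:
            finite = self.values[~np.isnan(self.values)]
            if finite.size and (finite.min() < SCALE_MIN - 1e-9 or finite.max() > SCALE_MAX + 1e-9):
                raise InvalidParameterError(
                    f"raw values outside [{SCALE_MIN}, {SCALE_MAX}] for "
                    f"{self.key}"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.rater_id, self.film_id, self.item_id)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    def copy_with(self, values: np.ndarray, state: str | None = None) -> "AnnotationSeries":
        return AnnotationSeries(
            rater_id=self.rater_id,
            film_id=self.film_id,
            item_id=self.item_id,
            values=np.asarray(values, dtype=float),
            state=self.state if state is None else state,
            sampling_rate=self.sampling_rate,
        )


@dataclass
class LatentSignal:
    """Smooth shared signal underlying all raters of one film x item.

    Standardized to zero mean and unit (population) SD at 1 Hz.
    """

    film_id: str
    item_id: str
    values: np.ndarray
    duration_s: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.duration_s:
            raise InvalidParameterError("latent length must equal duration_s")


@dataclass
class ClipRatingSet:
    """Sparse clip ratings for one subject x film x item.

    ``clips`` holds (onset_s, offset_s, value) triples on the 0-100 scale.
    """

    subject_id: str
    film_id: str
    item_id: str
    clips: list[tuple[float, float, float]]
    film_duration_s: float | None = None

    def __post_init__(self) -> None:
        for onset, offset, value in self.clips:
            if not onset < offset:
                raise InvalidClipError(f"clip onset {onset} not before offset {offset}")
            if not (SCALE_MIN <= value <= SCALE_MAX):
                raise InvalidClipError(f"clip value {value} outside [0, 100]")
            if self.film_duration_s is not None and (onset < 0 or offset > self.film_duration_s):
                raise InvalidClipError(
                    f"clip [{onset}, {offset}] outside film of {self.film_duration_s} s"
                )

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(on + off) / 2.0 for on, off, _ in self.clips])

    @property
    def ratings(self) -> np.ndarray:
        return np.array([v for _, _, v in self.clips])


@dataclass
class AgreementRecord:
    """All pairwise Pearson correlations among raters of one film x item."""

    film_id: str
    item_id: str
    pairwise_r: list[float]
    rater_pairs: list[tuple[str, str]]
    n_raters: int

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.pairwise_r))


@dataclass
class QCVerdict:
    """Per-series quality-control outcome."""

    rater_id: str
    film_id: str
    item_id: str
    flags: set[str] = field(default_factory=set)
    n_imputed: int = 0
    max_abs_z: float = float("nan")

    @property
    def usable(self) -> bool:
        return not ({"constant", "outlier"} & self.flags)


@dataclass
class ConsensusSeries:
    """Average of surviving z-scored rater series for one film x item."""

    film_id: str
    item_id: str
    values: np.ndarray
    n_raters: int
    contributing_raters: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean_level(self) -> float:
        """Time-average of the consensus trace (per film x item cell mean)."""
        return float(np.mean(self.values))


@dataclass
class ValidationRecord:
    """Correlation of the averaged clip-derived series with the consensus."""

    film_id: str
    item_id: str
    n_subjects: int
    r_with_consensus: float


@dataclass
class PhysioTrace:
    """A physiological recording (photoplethysmogram or respiration belt)."""

    modality: str
    sampling_rate: float
    values: np.ndarray
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.modality not in ("cardiac", "respiration"):
            raise InvalidParameterError(f"unsupported modality {self.modality!r}")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("trace contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sampling_rate


@dataclass
class PeakSet:
    """Detected event times (s) with the parameters that produced them."""

    times: np.ndarray
    detection_params: Mapping[str, float] = field(default_factory=dict)
    edit_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("peak times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class RegressorSeries:
    """A physiological nuisance regressor sampled at ``output_rate`` Hz."""

    kind: str
    values: np.ndarray
    output_rate: float
    window_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("HBI", "RV"):
            raise InvalidParameterError(f"unsupported regressor kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation with population denominators.

    The normalisation cancels between numerator and denominator, so this
    matches the textbook estimator; kept as one chokepoint so the
    minimum-overlap contract is enforced uniformly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AlignmentError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InvalidParameterError("Pearson r requires at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise InvalidParameterError("Pearson r undefined for zero-variance input")
    return float((xc * yc).sum() / denom)
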