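"""Clip-based validation of consensus annotations.

After scanning, subjects rated short excerpts (~21 clips per film, mean
7 s, roughly a fifth of each film's duration). Validation interpolates
those sparse ratings to a continuous 1 Hz series, z-scores and averages
them across the subjects who rated the item, and correlates the average
with the consensus annotation. The item-level meta-correlation then asks
whether items with low inter-rater agreement also validate poorly.

Each clip rating is anchored at the clip's temporal midpoint (the least
phase-biased choice for a rating of the whole clip); interpolation is
linear between anchors with constant extension beyond the terminal ones.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    EmptyInputError,
    InsufficientRatersError,
    InvalidParameterError,
)
from .types import ClipRatingSet, ConsensusSeries, ValidationRecord, pearson_r

MIN_SUBJECTS = 3


def interpolate_clip_series(clips: ClipRatingSet, film_duration_s: float) -> np.ndarray:
    """Continuous 1 Hz series from sparse clip ratings.

    Ratings are anchored at clip midpoints; values between anchors are
    linearly interpolated and held constant before the first and after
    the last anchor. Output has one sample per second of film.
    """
    if len(clips.clips) < 2:
        raise InsufficientRatersError(
            f"need at least 2 clips to interpolate, got {len(clips.clips)}"
        )
    mids = clips.midpoints
    if np.any(np.diff(mids) <= 0):
        raise InvalidParameterError("clips must be sorted and non-overlapping")
    t = np.arange(int(round(film_duration_s)), dtype=float)
    # np.interp extends with the terminal values, exactly the edge rule.
    return np.interp(t, mids, clips.ratings)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise InvalidParameterError("cannot z-score a constant series")
    return (x - x.mean()) / sd


def validate_item(
    subject_series: Sequence[np.ndarray],
    consensus: ConsensusSeries,
    min_subjects: int = MIN_SUBJECTS,
) -> ValidationRecord:
    """Correlate the subject-average interpolated series with the consensus.

    Each subject's interpolated series is z-scored (removing individual
    scale use), averaged across subjects, and Pearson-correlated with the
    consensus. Lengths may differ by at most one sample (trailing partial
    second); longer mismatches are alignment errors.
    """
    if len(subject_series) < min_subjects:
        raise InsufficientRatersError(
            f"need at least {min_subjects} subjects, got {len(subject_series)}"
        )
    lengths = {np.asarray(s).size for s in subject_series}
    if len(lengths) != 1:
        raise AlignmentError(f"subject series lengths differ: {sorted(lengths)}")
    n_sub = lengths.pop()
    n_con = consensus.values.size
    if abs(n_sub - n_con) > 1:
        raise AlignmentError(
            f"subject series ({n_sub}) and consensus ({n_con}) differ by more "
            "than one sample"
        )
    n = min(n_sub, n_con)
    if n_sub != n_con:
        warnings.warn(
            f"truncating to {n} samples (lengths {n_sub} vs {n_con})", stacklevel=2
        )
    avg = np.mean([_zscore(np.asarray(s, dtype=float)[:n]) for s in subject_series], axis=0)
    r = pearson_r(avg, consensus.values[:n])
    return ValidationRecord(
        film_id=consensus.film_id,
        item_id=consensus.item_id,
        n_subjects=len(subject_series),
        r_with_consensus=r,
    )


def meta_correlation(
    item_agreement_means: Mapping[str, float],
    item_validation_means: Mapping[str, float],
) -> float:
    """Pearson r between per-item agreement and per-item validation means.

    A positive value means items raters disagree on are also the items
    whose consensus the independent validation sample tracks least.
    """
    if not item_agreement_means or not item_validation_means:
        raise EmptyInputError("empty item-level vectors")
    keys_a = set(item_agreement_means)
    keys_v = set(item_validation_means)
    if keys_a != keys_v:
        raise AlignmentError(
            f"item sets differ: only-agreement={sorted(keys_a - keys_v)}, "
            f"only-validation={sorted(keys_v - keys_a)}"
        )
    items = sorted(keys_a)
    if len(items) < 3:
        raise InvalidParameterError("need at least 3 items for a meta-correlation")
    a = np.array([item_agreement_means[i] for i in items])
    v = np.array([item_validation_means[i] for i in items])
    return pearson_r(a, v)
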