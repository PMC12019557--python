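"""Per-series preprocessing and quality screens.

Order of operations, applied before any agreement computation:

1. z-score each series across the rater's films for one item (pooled
   normalisation removes the rater's personal gain and bias);
2. impute isolated missing samples from their two neighbours;
3. discard constant series (zero variance across the pooled films);
4. discard series containing samples beyond |z| = 15 (strict inequality).

z-scoring uses the population-SD convention (divide by N). Pooling is per
item, not across items, because items carry different pole meanings; the
``pool_items`` switch exposes the alternative reading.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .errors import StateError, UnsupportedGapError
from .types import RAW, ZSCORED, AnnotationSeries, QCVerdict

OUTLIER_Z_THRESHOLD = 15.0


def zscore_within_rater(
    series_set: Sequence[AnnotationSeries],
) -> tuple[list[AnnotationSeries], list[QCVerdict]]:
    """Normalise one rater's series for one item, pooled across films.

    The concatenation of all the rater's films for this item ends up with
    mean 0 and population SD 1; each film segment is returned separately in
    z-units. A zero-variance pooled concatenation yields a ``constant``
    verdict for every series of the group and no normalised output.
    """
    if not series_set:
        return [], []
    raters = {s.rater_id for s in series_set}
    items = {s.item_id for s in series_set}
    if len(raters) != 1 or len(items) != 1:
        raise StateError(
            f"zscore_within_rater expects one rater and one item, got raters "
            f"{sorted(raters)} items {sorted(items)}"
        )
    if any(s.state != RAW for s in series_set):
        raise StateError("series already z-scored")

    pooled = np.concatenate([s.values for s in series_set])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN safety
        mean = np.nanmean(pooled)
        sd = np.nanstd(pooled)  # population convention
    if not np.isfinite(sd) or sd == 0:
        verdicts = [
            QCVerdict(s.rater_id, s.film_id, s.item_id, flags={"constant"})
            for s in series_set
        ]
        return [], verdicts
    out = [s.copy_with((s.values - mean) / sd, state=ZSCORED) for s in series_set]
    return out, []


def impute_missing(series: AnnotationSeries, allow_gaps: bool = False) -> tuple[AnnotationSeries, int]:
    """Replace isolated missing samples by the mean of their neighbours.

    Edge samples copy the single nearest neighbour. Runs of two or more
    adjacent missing samples raise :class:`UnsupportedGapError` unless
    ``allow_gaps`` is set, in which case the gap is filled by linear
    interpolation and counted sample-by-sample.
    """
    values = series.values.copy()
    missing = np.where(np.isnan(values))[0]
    if missing.size == 0:
        return series, 0
    if np.isnan(values).all():
        raise UnsupportedGapError(f"series {series.key} is entirely missing")

    has_run = np.any(np.diff(missing) == 1)
    if has_run and not allow_gaps:
        raise UnsupportedGapError(
            f"series {series.key} has adjacent missing samples; "
            "two-neighbour imputation undefined (set allow_gaps for linear fill)"
        )
    if has_run:
        idx = np.arange(values.size)
        good = ~np.isnan(values)
        values = np.interp(idx, idx[good], values[good])
    else:
        for i in missing:
            if i == 0:
                values[i] = values[i + 1]
            elif i == values.size - 1:
                values[i] = values[i - 1]
            else:
                values[i] = 0.5 * (values[i - 1] + values[i + 1])
    return series.copy_with(values), int(missing.size)


def screen_constant(series: AnnotationSeries) -> bool:
    """True when the series is flat (zero variance ignoring missing)."""
    finite = series.values[~np.isnan(series.values)]
    return finite.size == 0 or bool(np.all(finite == finite[0]))


def screen_outliers(series: AnnotationSeries, threshold: float = OUTLIER_Z_THRESHOLD) -> QCVerdict:
    """Flag series containing samples strictly beyond ``|z| = threshold``."""
    if series.state != ZSCORED:
        raise StateError("outlier screen requires a z-scored series")
    max_abs_z = float(np.nanmax(np.abs(series.values)))
    verdict = QCVerdict(series.rater_id, series.film_id, series.item_id,
                        max_abs_z=max_abs_z)
    if max_abs_z > threshold:
        verdict.flags.add("outlier")
    return verdict


def run_qc(
    series: Iterable[AnnotationSeries],
    outlier_threshold: float = OUTLIER_Z_THRESHOLD,
    allow_gaps: bool = False,
    pool_items: bool = False,
) -> tuple[list[AnnotationSeries], list[QCVerdict]]:
    """Full per-series QC: z-score, impute, constant screen, outlier screen.

    Returns the surviving z-scored series and one verdict per input
    series. Grouping for normalisation is per (rater, item) across films,
    or per rater across everything when ``pool_items`` is set.
    """
    groups: dict[tuple, list[AnnotationSeries]] = defaultdict(list)
    for s in series:
        key = (s.rater_id,) if pool_items else (s.rater_id, s.item_id)
        groups[key].append(s)

    survivors: list[AnnotationSeries] = []
    verdicts: list[QCVerdict] = []
    for key in sorted(groups):
        group = groups[key]
        zs, const_verdicts = _zscore_group(group, pool_items)
        verdicts.extend(const_verdicts)
        for z in zs:
            z, n_imp = impute_missing(z, allow_gaps=allow_gaps)
            if screen_constant(z):
                v = QCVerdict(z.rater_id, z.film_id, z.item_id,
                              flags={"constant"}, n_imputed=n_imp)
                verdicts.append(v)
                continue
            v = screen_outliers(z, threshold=outlier_threshold)
            v.n_imputed = n_imp
            if n_imp:
                v.flags.add("imputed")
            verdicts.append(v)
            if v.usable:
                survivors.append(z)
    return survivors, verdicts


def _zscore_group(group, pool_items):
    if pool_items:
        # Pool everything the rater annotated; reuse the per-item code path
        # by temporarily treating the group as one item.
        pooled = np.concatenate([s.values for s in group])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean, sd = np.nanmean(pooled), np.nanstd(pooled)
        if not np.isfinite(sd) or sd == 0:
            return [], [QCVerdict(s.rater_id, s.film_id, s.item_id, flags={"constant"})
                        for s in group]
        return [s.copy_with((s.values - mean) / sd, state=ZSCORED) for s in group], []
    return zscore_within_rater(group)
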