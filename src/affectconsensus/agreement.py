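"""Inter-rater agreement and the rater-exclusion cascade.

Agreement for one film x item is the arithmetic mean of all pairwise
Pearson correlations among that combo's raters. Screened series then pass
through two further exclusion rules:

- *deviance exclusion*: a series is dropped when dropping it raises the
  remaining raters' mean pairwise correlation by more than 0.20, never
  going below a floor of 3 survivors. Applied greedily, recomputing after
  each removal.
- *worst of five*: combos that still hold five series lose the one with
  the lowest average correlation to the others.

Item- and film-level reliability gating operates on the film x item mean
agreement matrix: items with mean across films below 0.15 are removed
(flagged unreliable below 0.20), films with mean across items below 0.25
are removed.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InsufficientRatersError, InvalidParameterError
from .types import ZSCORED, AgreementRecord, AnnotationSeries, pearson_r

DEVIANCE_DELTA = 0.20
RATER_FLOOR = 3
ITEM_REMOVE_THRESHOLD = 0.15
ITEM_FLAG_THRESHOLD = 0.20
FILM_REMOVE_THRESHOLD = 0.25


def _check_combo(series_set: Sequence[AnnotationSeries]) -> None:
    films = {s.film_id for s in series_set}
    items = {s.item_id for s in series_set}
    if len(films) != 1 or len(items) != 1:
        raise InvalidParameterError("series must share one film and one item")
    lengths = {s.n_samples for s in series_set}
    if len(lengths) != 1:
        raise InvalidParameterError(f"unequal series lengths {sorted(lengths)}")


def pairwise_agreement(series_set: Sequence[AnnotationSeries]) -> AgreementRecord:
    """All unordered-pair Pearson correlations for one film x item.

    With four raters this yields six r values; their mean is the combo's
    agreement. Input series must already be z-scored survivors of QC.
    """
    if len(series_set) < 2:
        raise InsufficientRatersError(
            f"need at least 2 series, got {len(series_set)}"
        )
    _check_combo(series_set)
    if any(s.state != ZSCORED for s in series_set):
        raise InvalidParameterError("agreement requires z-scored series")
    ordered = sorted(series_set, key=lambda s: s.rater_id)
    pairs, rs = [], []
    for a, b in itertools.combinations(ordered, 2):
        pairs.append((a.rater_id, b.rater_id))
        rs.append(pearson_r(a.values, b.values))
    return AgreementRecord(
        film_id=ordered[0].film_id,
        item_id=ordered[0].item_id,
        pairwise_r=rs,
        rater_pairs=pairs,
        n_raters=len(ordered),
    )


def _mean_pairwise_r(series_set: Sequence[AnnotationSeries]) -> float:
    return pairwise_agreement(series_set).mean_r


@dataclass
class Removal:
    """One step of the exclusion cascade for one film x item."""

    rater_id: str
    film_id: str
    item_id: str
    reason: str
    improvement: float = float("nan")


def deviance_exclusion(
    series_set: Sequence[AnnotationSeries],
    delta: float = DEVIANCE_DELTA,
    floor: int = RATER_FLOOR,
) -> tuple[list[AnnotationSeries], list[Removal]]:
    """Greedy leave-one-out exclusion of agreement-reducing series.

    At each step the series whose removal most increases the remaining
    mean pairwise r is dropped, provided the increase exceeds ``delta``
    and at least ``floor`` series would remain. Ties break on
    lexicographically smallest rater_id.
    """
    if floor < 2:
        raise InvalidParameterError("floor must be at least 2")
    if len(series_set) < floor:
        raise InsufficientRatersError(
            f"need at least floor={floor} series, got {len(series_set)}"
        )
    survivors = sorted(series_set, key=lambda s: s.rater_id)
    removed: list[Removal] = []
    while len(survivors) > floor:
        base = _mean_pairwise_r(survivors)
        best_idx, best_gain = None, -np.inf
        for i in range(len(survivors)):
            rest = survivors[:i] + survivors[i + 1:]
            gain = _mean_pairwise_r(rest) - base
            if gain > best_gain + 1e-12:  # first (lexicographically) wins ties
                best_idx, best_gain = i, gain
        if best_gain <= delta:
            break
        worst = survivors.pop(best_idx)
        removed.append(Removal(worst.rater_id, worst.film_id, worst.item_id,
                               reason="deviant", improvement=float(best_gain)))
    return survivors, removed


def worst_of_five(
    series_set: Sequence[AnnotationSeries],
) -> tuple[list[AnnotationSeries], list[Removal]]:
    """Drop the least-agreeing series from a five-rater combo.

    The series with the lowest mean correlation to the other four is
    removed; ties resolve by removing the lexicographically last
    rater_id. Combos of any other size pass through unchanged with a
    warning.
    """
    if len(series_set) != 5:
        warnings.warn(
            f"worst_of_five called with {len(series_set)} series; no-op",
            stacklevel=2,
        )
        return list(series_set), []
    ordered = sorted(series_set, key=lambda s: s.rater_id)
    mean_to_others = []
    for i, s in enumerate(ordered):
        rest = ordered[:i] + ordered[i + 1:]
        mean_to_others.append(np.mean([pearson_r(s.values, o.values) for o in rest]))
    lowest = min(mean_to_others)
    # Lexicographically last among ties: iterate from the end.
    idx = max(i for i, m in enumerate(mean_to_others) if m <= lowest + 1e-12)
    worst = ordered[idx]
    removed = [Removal(worst.rater_id, worst.film_id, worst.item_id, reason="worst_of_five")]
    return ordered[:idx] + ordered[idx + 1:], removed


@dataclass
class ExclusionLedger:
    """Per-reason removal counts with the conservation identity enforced."""

    n_available: int = 0
    removals: list[Removal] = field(default_factory=list)
    survivors_per_combo: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def counts_by_reason(self) -> dict[str, int]:
        return dict(Counter(r.reason for r in self.removals))

    @property
    def n_survivors(self) -> int:
        return sum(self.survivors_per_combo.values())

    def check(self) -> None:
        from .errors import LedgerError

        removed = len(self.removals)
        if self.n_available - removed != self.n_survivors:
            raise LedgerError(
                f"ledger identity violated: {self.n_available} available - "
                f"{removed} removed != {self.n_survivors} survivors"
            )


@dataclass
class GatingReport:
    """Item/film reliability gating outcome over the full design."""

    item_means: pd.Series
    film_means: pd.Series
    removed_items: list[str]
    flagged_items: list[str]
    removed_films: list[str]

    def surviving(self, records: Iterable[AgreementRecord]) -> list[AgreementRecord]:
        return [
            r for r in records
            if r.item_id not in self.removed_items and r.film_id not in self.removed_films
        ]


def agreement_table(records: Iterable[AgreementRecord]) -> pd.DataFrame:
    """Film x item matrix of mean pairwise agreement."""
    records = list(records)
    if not records:
        raise EmptyInputError("no agreement records")
    df = pd.DataFrame(
        {"film": r.film_id, "item": r.item_id, "mean_r": r.mean_r} for r in records
    )
    return df.pivot(index="film", columns="item", values="mean_r")


def item_film_gating(
    records: Iterable[AgreementRecord],
    item_remove: float = ITEM_REMOVE_THRESHOLD,
    item_flag: float = ITEM_FLAG_THRESHOLD,
    film_remove: float = FILM_REMOVE_THRESHOLD,
) -> GatingReport:
    """Gate unreliable items and films on their marginal mean agreement.

    Item means are taken across films and film means across items, from
    the full film x item agreement matrix. Items below ``item_remove``
    are removed; items below ``item_flag`` (but not removed) are flagged
    unreliable; films below ``film_remove`` are removed. Film means are
    recomputed without removed items before film gating, so a handful of
    bad items cannot sink a film.
    """
    table = agreement_table(records)
    item_means = table.mean(axis=0)
    removed_items = sorted(item_means.index[item_means < item_remove])
    flagged_items = sorted(
        item_means.index[(item_means >= item_remove) & (item_means < item_flag)]
    )
    kept = table.drop(columns=removed_items)
    film_means = kept.mean(axis=1)
    removed_films = sorted(film_means.index[film_means < film_remove])
    return GatingReport(
        item_means=item_means,
        film_means=film_means,
        removed_items=removed_items,
        flagged_items=flagged_items,
        removed_films=removed_films,
    )
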