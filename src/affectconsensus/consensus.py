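"""Consensus construction and exclusion-ledger reconciliation.

The consensus annotation for one film x item is the pointwise arithmetic
mean of the surviving z-scored rater series — at least three of them. The
average is deliberately not re-standardised: its variance shrinks with the
noise level and rater count (for n raters at noise-to-signal ratio
sigma_n^2/sigma_s^2 the consensus-latent correlation is
1 / sqrt(1 + sigma_n^2 / (n sigma_s^2))), and that agreement-dependent
variance is informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InsufficientRatersError, InvalidParameterError, LedgerError
from .types import ZSCORED, AnnotationSeries, ConsensusSeries

CONSENSUS_FLOOR = 3


def build_consensus(survivors: Sequence[AnnotationSeries]) -> ConsensusSeries:
    """Average the surviving z-scored series of one film x item."""
    if len(survivors) < CONSENSUS_FLOOR:
        raise InsufficientRatersError(
            f"consensus needs at least {CONSENSUS_FLOOR} series for "
            f"{survivors[0].film_id if survivors else '?'} x "
            f"{survivors[0].item_id if survivors else '?'}, got {len(survivors)}"
        )
    films = {s.film_id for s in survivors}
    items = {s.item_id for s in survivors}
    if len(films) != 1 or len(items) != 1:
        raise InvalidParameterError("survivors must share one film and one item")
    if any(s.state != ZSCORED for s in survivors):
        raise InvalidParameterError("consensus requires z-scored series")
    lengths = {s.n_samples for s in survivors}
    if len(lengths) != 1:
        raise InvalidParameterError(f"unequal series lengths {sorted(lengths)}")
    ordered = sorted(survivors, key=lambda s: s.rater_id)
    values = np.mean([s.values for s in ordered], axis=0)
    return ConsensusSeries(
        film_id=ordered[0].film_id,
        item_id=ordered[0].item_id,
        values=values,
        n_raters=len(ordered),
        contributing_raters=[s.rater_id for s in ordered],
    )


@dataclass
class LedgerSummary:
    """Counts from reconciling removals against the design arithmetic."""

    n_available: int
    n_removed: int
    n_survivors: int
    n_combos: int
    combos_with_three: int
    combos_with_four: int


def reconcile_ledger(
    n_available: int,
    removals_by_reason: Mapping[str, int],
    n_combos: int,
) -> LedgerSummary:
    """Derive the 3- vs 4-rater combo split from the removal counts.

    Under the design constraint that every combo retains exactly three or
    four series, survivors = available - removals, and the number of
    three-rater combos is 4*n_combos - survivors. Inconsistent counts
    (negative, or outside [0, n_combos]) raise :class:`LedgerError` naming
    the violated identity.
    """
    if n_available < 0 or n_combos < 0 or any(v < 0 for v in removals_by_reason.values()):
        raise LedgerError("counts must be non-negative")
    n_removed = sum(removals_by_reason.values())
    n_survivors = n_available - n_removed
    if n_survivors < 0:
        raise LedgerError(
            f"removals ({n_removed}) exceed available series ({n_available})"
        )
    combos_with_three = 4 * n_combos - n_survivors
    combos_with_four = n_combos - combos_with_three
    if not 0 <= combos_with_three <= n_combos:
        raise LedgerError(
            f"identity violated: 4*{n_combos} - {n_survivors} = "
            f"{combos_with_three} three-rater combos is outside [0, {n_combos}] "
            "(each combo must retain 3 or 4 series)"
        )
    return LedgerSummary(
        n_available=n_available,
        n_removed=n_removed,
        n_survivors=n_survivors,
        n_combos=n_combos,
        combos_with_three=combos_with_three,
        combos_with_four=combos_with_four,
    )


def mean_level_table(consensus_list: Sequence[ConsensusSeries]):
    """Film x item table of consensus time-averages (relative intensity)."""
    import pandas as pd

    df = pd.DataFrame(
        {"film": c.film_id, "item": c.item_id, "mean_level": c.mean_level}
        for c in consensus_list
    )
    return df.pivot(index="film", columns="item", values="mean_level")
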