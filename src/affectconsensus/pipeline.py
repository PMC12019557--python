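"""End-to-end consensus pipeline: QC -> agreement -> exclusions -> consensus.

Glues the stage modules together for whole-dataset runs. The default
order follows the processing recipe: per-rater z-scoring and screens
first, then reliability gating of items and films on the screened
agreement matrix, then the per-combo exclusion cascade (deviance, then
worst-of-five) and consensus averaging on what survives. Gating can be
switched to run after the cascade via ``gate_first=False``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .agreement import (
    ExclusionLedger,
    GatingReport,
    Removal,
    deviance_exclusion,
    item_film_gating,
    pairwise_agreement,
    worst_of_five,
)
from .consensus import CONSENSUS_FLOOR, build_consensus
from .errors import InsufficientRatersError
from .qc import run_qc
from .types import AgreementRecord, AnnotationSeries, ConsensusSeries, QCVerdict


@dataclass
class PipelineResult:
    """Everything a pipeline run produces, for auditing and writing out."""

    consensus: list[ConsensusSeries]
    agreement_before: list[AgreementRecord]
    agreement_after: list[AgreementRecord]
    gating: GatingReport | None
    ledger: ExclusionLedger
    qc_verdicts: list[QCVerdict]
    rejected_combos: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def mean_agreement(self) -> float:
        import numpy as np

        return float(np.mean([r.mean_r for r in self.agreement_after]))


def run_pipeline(
    series: Iterable[AnnotationSeries],
    deviance_delta: float = 0.20,
    floor: int = CONSENSUS_FLOOR,
    gate: bool = True,
    gate_first: bool = True,
    allow_gaps: bool = False,
) -> PipelineResult:
    """Run the full consensus pipeline over a set of raw annotation series.

    Combos left with fewer than ``floor`` series after screening are
    reported in ``rejected_combos`` rather than silently dropped; the
    exclusion ledger's conservation identity is checked before returning.
    """
    series = list(series)
    screened, verdicts = run_qc(series, allow_gaps=allow_gaps)

    ledger = ExclusionLedger(n_available=len(series))
    for v in verdicts:
        for reason in ("constant", "outlier"):
            if reason in v.flags:
                ledger.removals.append(Removal(v.rater_id, v.film_id, v.item_id, reason))

    combos: dict[tuple[str, str], list[AnnotationSeries]] = defaultdict(list)
    for s in screened:
        combos[(s.film_id, s.item_id)].append(s)

    agreement_before = [
        pairwise_agreement(group) for group in
        (combos[k] for k in sorted(combos)) if len(group) >= 2
    ]

    gating: GatingReport | None = None
    if gate and gate_first:
        gating = item_film_gating(agreement_before)
        combos = {
            k: v for k, v in combos.items()
            if k[1] not in gating.removed_items and k[0] not in gating.removed_films
        }
        # Series gated away leave the ledger's scope entirely.
        ledger.n_available = sum(len(v) for v in combos.values()) + sum(
            1 for r in ledger.removals
            if r.item_id not in gating.removed_items and r.film_id not in gating.removed_films
        )
        ledger.removals = [
            r for r in ledger.removals
            if r.item_id not in gating.removed_items and r.film_id not in gating.removed_films
        ]

    consensus_list: list[ConsensusSeries] = []
    rejected: list[tuple[str, str, int]] = []
    for key in sorted(combos):
        film, item = key
        group = combos[key]
        if len(group) < floor:
            rejected.append((film, item, len(group)))
            ledger.survivors_per_combo[key] = len(group)
            continue
        survivors, removed = deviance_exclusion(group, delta=deviance_delta, floor=floor)
        ledger.removals.extend(removed)
        if len(survivors) == 5:
            survivors, removed5 = worst_of_five(survivors)
            ledger.removals.extend(removed5)
        ledger.survivors_per_combo[key] = len(survivors)
        consensus_list.append(build_consensus(survivors))
        combos[key] = survivors

    agreement_after = []
    for key in sorted(combos):
        if ledger.survivors_per_combo.get(key, 0) >= 2:
            agreement_after.append(pairwise_agreement(combos[key]))

    if gate and not gate_first and agreement_after:
        gating = item_film_gating(agreement_after)
        keep = lambda c: (c.item_id not in gating.removed_items
                          and c.film_id not in gating.removed_films)  # noqa: E731
        consensus_list = [c for c in consensus_list if keep(c)]
        agreement_after = [r for r in agreement_after if keep(r)]
        ledger.n_available = sum(
            n for (f, i), n in ledger.survivors_per_combo.items()
            if i not in gating.removed_items and f not in gating.removed_films
        ) + sum(
            1 for r in ledger.removals
            if r.item_id not in gating.removed_items and r.film_id not in gating.removed_films
        )
        ledger.removals = [
            r for r in ledger.removals
            if r.item_id not in gating.removed_items and r.film_id not in gating.removed_films
        ]
        ledger.survivors_per_combo = {
            (f, i): n for (f, i), n in ledger.survivors_per_combo.items()
            if i not in gating.removed_items and f not in gating.removed_films
        }

    ledger.check()
    return PipelineResult(
        consensus=consensus_list,
        agreement_before=agreement_before,
        agreement_after=agreement_after,
        gating=gating,
        ledger=ledger,
        qc_verdicts=verdicts,
        rejected_combos=rejected,
    )
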