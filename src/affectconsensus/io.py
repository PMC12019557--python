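"""Tabular readers and writers plus assignment-grid generation.

Layout is BIDS-inspired: one TSV per rater x film x item named
``sub-<rater>_task-<film>_item-<item>_annot.tsv`` whose header row names
film, item and rater; one value row per second of film (row index =
second, 0-based); missing samples serialized as ``n/a``. Consensus output
is one TSV per film with an item column each, plus a JSON sidecar holding
per-item rater counts and exclusion history.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnnotationParseError,
    DuplicateRecordError,
    EmptyInputError,
    InfeasibleGridError,
    InvalidParameterError,
    OverwriteError,
)
from .types import AnnotationSeries, ConsensusSeries

MISSING_TOKEN = "n/a"
_ANNOT_STEM = re.compile(r"^sub-(?P<rater>[^_]+)_task-(?P<film>[^_]+)_item-(?P<item>[^_]+)_annot$")

#: The six response-component categories items are drawn from.
ITEM_COMPONENTS = (
    "appraisal",
    "motivation",
    "expression",
    "physiology",
    "feeling",
    "discrete_emotion",
)


def annotation_filename(rater_id: str, film_id: str, item_id: str) -> str:
    return f"sub-{rater_id}_task-{film_id}_item-{item_id}_annot.tsv"


def write_annotations(
    series: Iterable[AnnotationSeries], path: str | Path, overwrite: bool = False
) -> list[Path]:
    """One TSV per series, missing samples as ``n/a``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for s in series:
        fp = path / annotation_filename(s.rater_id, s.film_id, s.item_id)
        if fp.exists() and not overwrite:
            raise OverwriteError(f"{fp} exists; pass overwrite=True to replace")
        col = [MISSING_TOKEN if np.isnan(v) else format(v, ".6g") for v in s.values]
        df = pd.DataFrame({"film": s.film_id, "item": s.item_id,
                           "rater": s.rater_id, "value": col})
        df.to_csv(fp, sep="\t", index=False)
        written.append(fp)
    return written


def read_annotations(path: str | Path) -> list[AnnotationSeries]:
    """Parse every ``*_annot.tsv`` under ``path``.

    Non-numeric cells raise :class:`AnnotationParseError` with file and
    line; the same rater x film x item twice raises
    :class:`DuplicateRecordError`; a directory without annotation files,
    or a file without data rows, raises :class:`EmptyInputError`.
    """
    path = Path(path)
    files = sorted(path.rglob("*_annot.tsv"))
    if not files:
        raise EmptyInputError(f"no *_annot.tsv files under {path}")
    seen: set[tuple[str, str, str]] = set()
    out: list[AnnotationSeries] = []
    for fp in files:
        m = _ANNOT_STEM.match(fp.stem)
        if m is None:
            raise AnnotationParseError(f"{fp}: filename does not match the annotation pattern")
        try:
            df = pd.read_csv(fp, sep="\t", dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"{fp}: file is empty") from None
        if df.empty:
            raise EmptyInputError(f"{fp}: no data rows")
        for col in ("film", "item", "rater", "value"):
            if col not in df.columns:
                raise AnnotationParseError(f"{fp}: missing column {col!r}")
        rater, film, item = m["rater"], m["film"], m["item"]
        header_ids = (df["rater"].iloc[0], df["film"].iloc[0], df["item"].iloc[0])
        if header_ids != (rater, film, item):
            raise AnnotationParseError(
                f"{fp}: header identifiers {header_ids} disagree with filename"
            )
        key = (rater, film, item)
        if key in seen:
            raise DuplicateRecordError(f"{fp}: duplicate record for {key}")
        seen.add(key)
        values = np.empty(len(df))
        for i, cell in enumerate(df["value"]):
            if cell == MISSING_TOKEN or cell == "":
                values[i] = np.nan
            else:
                try:
                    values[i] = float(cell)
                except ValueError:
                    raise AnnotationParseError(
                        f"{fp}: line {i + 2}: non-numeric value {cell!r}"
                    ) from None
        out.append(AnnotationSeries(rater_id=rater, film_id=film, item_id=item, values=values))
    return out


def write_consensus(
    path: str | Path,
    consensus: Sequence[ConsensusSeries],
    exclusion_history: Mapping[tuple[str, str], list[dict]] | None = None,
    overwrite: bool = False,
) -> list[Path]:
    """One TSV per film (one column per item) plus a JSON sidecar.

    The sidecar records, per item column, the number of contributing
    raters and the exclusion history supplied for that film x item.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    by_film: dict[str, list[ConsensusSeries]] = {}
    for c in consensus:
        by_film.setdefault(c.film_id, []).append(c)
    written = []
    for film, cols in sorted(by_film.items()):
        fp = path / f"task-{film}_consensus.tsv"
        side = path / f"task-{film}_consensus.json"
        if (fp.exists() or side.exists()) and not overwrite:
            raise OverwriteError(f"{fp} exists; pass overwrite=True to replace")
        cols = sorted(cols, key=lambda c: c.item_id)
        df = pd.DataFrame({c.item_id: c.values for c in cols})
        df.to_csv(fp, sep="\t", index=False, float_format="%.6g")
        meta = {
            c.item_id: {
                "n_raters": c.n_raters,
                "contributing_raters": c.contributing_raters,
                "exclusion_history": (exclusion_history or {}).get((film, c.item_id), []),
            }
            for c in cols
        }
        side.write_text(json.dumps(meta, indent=2))
        written.extend([fp, side])
    return written


def read_consensus(path: str | Path, film_id: str) -> dict[str, ConsensusSeries]:
    """Read one film's consensus TSV + sidecar back into series objects."""
    path = Path(path)
    fp = path / f"task-{film_id}_consensus.tsv"
    meta = json.loads((path / f"task-{film_id}_consensus.json").read_text())
    df = pd.read_csv(fp, sep="\t")
    out = {}
    for item in df.columns:
        out[item] = ConsensusSeries(
            film_id=film_id,
            item_id=item,
            values=df[item].to_numpy(),
            n_raters=meta[item]["n_raters"],
            contributing_raters=meta[item]["contributing_raters"],
        )
    return out


@dataclass
class AssignmentGrid:
    """Which rater annotates which film x item.

    ``lists`` maps each rater list to its assigned items; each rater's
    tasks are that item set crossed with every film, sorted in blocks by
    item (one item across all films before the next item).
    """

    lists: dict[str, list[str]]
    films: list[str]
    item_components: dict[str, str] = field(default_factory=dict)

    @property
    def assignments(self) -> dict[str, set[tuple[str, str]]]:
        return {
            rater: {(film, item) for item in items for film in self.films}
            for rater, items in self.lists.items()
        }

    def tasks(self, rater_id: str) -> list[tuple[str, str]]:
        """(film, item) tasks for one rater, blocked by item."""
        return [(film, item) for item in self.lists[rater_id] for film in self.films]

    def raters_for(self, film_id: str, item_id: str) -> list[str]:
        return sorted(r for r, items in self.lists.items() if item_id in items)

    def coverage(self) -> dict[str, int]:
        """Number of raters assigned to each item."""
        cov: dict[str, int] = {}
        for items in self.lists.values():
            for item in items:
                cov[item] = cov.get(item, 0) + 1
        return cov


def build_assignment_grid(
    items: Sequence[str],
    films: Sequence[str],
    n_lists: int,
    items_per_list: int,
    n_raters_per_item: int = 4,
    seed: int = 0,
    item_components: Mapping[str, str] | None = None,
) -> AssignmentGrid:
    """Randomly assign items to rater lists at the required coverage.

    Items are shuffled once and cycled ``n_raters_per_item`` times
    through consecutive list slots; surplus slots (when
    n_lists * items_per_list exceeds items * coverage) hand extra raters
    to the leading items of the shuffle. Cutting the cycled sequence into
    list-sized chunks guarantees no rater sees the same item twice as
    long as items_per_list <= number of items.
    """
    items = list(items)
    if items_per_list > len(items):
        raise InfeasibleGridError(
            f"items_per_list={items_per_list} exceeds the {len(items)} items"
        )
    if len(set(items)) != len(items):
        raise InvalidParameterError("duplicate item identifiers")
    slots = n_lists * items_per_list
    needed = len(items) * n_raters_per_item
    if slots < needed:
        raise InfeasibleGridError(
            f"{n_lists} lists x {items_per_list} items provide {slots} slots "
            f"but coverage of {n_raters_per_item} raters over {len(items)} "
            f"items needs {needed} (short by {needed - slots})"
        )
    extra = slots - needed
    if extra > len(items):
        raise InfeasibleGridError(
            f"{extra} surplus slots exceed the item count; reduce n_lists or "
            "items_per_list"
        )
    rng = np.random.default_rng(seed)
    order = [str(x) for x in rng.permutation(items)]
    sequence = order * n_raters_per_item + order[:extra]
    lists = {
        f"list-{i + 1:02d}": sequence[i * items_per_list : (i + 1) * items_per_list]
        for i in range(n_lists)
    }
    for rater, assigned in lists.items():
        if len(set(assigned)) != len(assigned):
            # Only possible when the extra block wraps onto the cycle tail.
            raise InfeasibleGridError(f"{rater} would receive a repeated item")
    return AssignmentGrid(
        lists=lists,
        films=list(films),
        item_components=dict(item_components or {}),
    )


def write_physio(trace_values, sampling_rate: float, modality: str, path: str | Path) -> Path:
    """Plain-TSV physiological trace with a JSON sidecar (BIDS-style)."""
    path = Path(path)
    pd.DataFrame({modality: np.asarray(trace_values)}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"SamplingFrequency": sampling_rate, "Columns": [modality]}))
    return path
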