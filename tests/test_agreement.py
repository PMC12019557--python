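"""Pairwise agreement, the exclusion cascade (with a brute-force oracle),
and item/film reliability gating."""

import numpy as np
import pytest

import affectconsensus as ac
from affectconsensus.agreement import (
    deviance_exclusion,
    item_film_gating,
    pairwise_agreement,
    worst_of_five,
)
from affectconsensus.errors import InsufficientRatersError, InvalidParameterError
from affectconsensus.types import ZSCORED, AgreementRecord, AnnotationSeries, pearson_r


def zseries(values, rater, film="f1", item="i1"):
    v = np.asarray(values, float)
    return AnnotationSeries(rater, film, item, (v - v.mean()) / v.std(), state=ZSCORED)


def noise_series(rater, n=200, seed=0, film="f1", item="i1"):
    rng = np.random.default_rng(seed)
    return zseries(rng.standard_normal(n), rater, film, item)


class TestPairwiseAgreement:
    def test_four_identical_series_give_six_unit_correlations(self):
        base = np.sin(np.linspace(0, 10, 100))
        rec = pairwise_agreement([zseries(base, f"r{k}") for k in range(4)])
        assert len(rec.pairwise_r) == 6
        assert rec.mean_r == pytest.approx(1.0)
        assert rec.n_raters == 4

    def test_negated_pair(self):
        base = np.sin(np.linspace(0, 10, 100))
        rec = pairwise_agreement([zseries(base, "a"), zseries(-base, "b")])
        assert rec.pairwise_r[0] == pytest.approx(-1.0)

    def test_pair_count_formula(self):
        base = np.cos(np.linspace(0, 7, 80))
        rng = np.random.default_rng(1)
        for n in (2, 3, 5):
            group = [zseries(base + rng.normal(0, 0.5, 80), f"r{k}") for k in range(n)]
            rec = pairwise_agreement(group)
            assert len(rec.pairwise_r) == n * (n - 1) // 2

    def test_simulated_target_agreement_recovered(self, make_combo):
        means = []
        for seed in range(30):
            zs, _ = make_combo(target_agreement=0.5, seed=seed)
            means.append(pairwise_agreement(zs).mean_r)
        assert np.mean(means) == pytest.approx(0.5, abs=0.05)

    def test_single_series_rejected(self):
        with pytest.raises(InsufficientRatersError):
            pairwise_agreement([noise_series("a")])


def oracle_terminal_sets(series_set, delta=0.20, floor=3):
    """All terminal survivor sets reachable by any order of single removals
    each improving mean r by > delta while keeping >= floor series."""
    terminals = set()

    def recurse(current):
        moves = []
        if len(current) > floor:
            base = pairwise_agreement(list(current)).mean_r
            for s in current:
                rest = [x for x in current if x is not s]
                if pairwise_agreement(rest).mean_r - base > delta:
                    moves.append(s)
        if not moves:
            terminals.add(frozenset(x.rater_id for x in current))
            return
        for s in moves:
            recurse(tuple(x for x in current if x is not s))

    recurse(tuple(series_set))
    return terminals


class TestDevianceExclusion:
    def test_noise_rater_among_clones_removed(self):
        base = np.sin(np.linspace(0, 20, 300))
        group = [zseries(base, f"r{k}") for k in range(3)] + [noise_series("r9", 300, seed=4)]
        survivors, removed = deviance_exclusion(group)
        assert [r.rater_id for r in removed] == ["r9"]
        assert removed[0].improvement > 0.20
        assert len(survivors) == 3

    def test_identical_series_nothing_removed(self):
        base = np.sin(np.linspace(0, 20, 300))
        survivors, removed = deviance_exclusion([zseries(base, f"r{k}") for k in range(4)])
        assert removed == []
        assert len(survivors) == 4

    def test_floor_protects_three_series(self):
        # Three series, one pure noise: its removal would raise mean r far
        # beyond 0.20 but would leave two series, so it must be retained.
        base = np.sin(np.linspace(0, 20, 300))
        group = [zseries(base, "r0"), zseries(base, "r1"), noise_series("r9", 300, seed=2)]
        survivors, removed = deviance_exclusion(group)
        assert removed == []
        assert len(survivors) == 3

    def test_invalid_floor(self):
        with pytest.raises(InvalidParameterError):
            deviance_exclusion([noise_series(f"r{k}", seed=k) for k in range(4)], floor=1)

    def test_greedy_matches_exhaustive_oracle_on_seeded_instances(self, make_combo):
        """The greedy cascade lands on a terminal set of the removal relation,
        and on the unique one whenever the relation is confluent."""
        for seed in range(25):
            n = 4 + seed % 2
            contamination = {0: "deviant"} if seed % 3 else None
            zs, _ = make_combo(
                n_raters=n, duration_s=300, target_agreement=0.45,
                seed=100 + seed, contamination=contamination,
            )
            survivors, _ = deviance_exclusion(zs)
            got = frozenset(s.rater_id for s in survivors)
            terminals = oracle_terminal_sets(zs)
            assert got in terminals
            if len(terminals) == 1:
                assert got == next(iter(terminals))

    def test_removal_never_decreases_mean_r(self, make_combo):
        zs, _ = make_combo(n_raters=5, seed=3, contamination={2: "deviant"})
        before = pairwise_agreement(zs).mean_r
        survivors, removed = deviance_exclusion(zs)
        if removed:
            assert pairwise_agreement(survivors).mean_r > before


class TestWorstOfFive:
    def test_noise_series_removed(self):
        base = np.sin(np.linspace(0, 20, 300))
        group = [zseries(base + np.random.default_rng(k).normal(0, 0.3, 300), f"r{k}")
                 for k in range(4)] + [noise_series("r9", 300, seed=1)]
        survivors, removed = worst_of_five(group)
        assert [r.rater_id for r in removed] == ["r9"]
        assert len(survivors) == 4

    def test_tie_removes_lexicographically_last(self):
        base = np.sin(np.linspace(0, 20, 100))
        group = [zseries(base, f"r{k}") for k in range(5)]
        survivors, removed = worst_of_five(group)
        assert removed[0].rater_id == "r4"

    def test_non_five_is_noop_with_warning(self):
        base = np.sin(np.linspace(0, 20, 100))
        group = [zseries(base, f"r{k}") for k in range(4)]
        with pytest.warns(UserWarning):
            survivors, removed = worst_of_five(group)
        assert len(survivors) == 4 and removed == []


def record(film, item, mean_r):
    return AgreementRecord(film, item, [mean_r], [("a", "b")], 2)


class TestGating:
    def test_item_below_remove_threshold_removed(self):
        records = [record(f"f{k}", "bad", 0.10) for k in range(3)]
        records += [record(f"f{k}", "good", 0.50) for k in range(3)]
        rep = item_film_gating(records)
        assert rep.removed_items == ["bad"]
        assert rep.flagged_items == []
        assert rep.removed_films == []

    def test_item_between_thresholds_flagged_not_removed(self):
        records = [record(f"f{k}", "soso", 0.17) for k in range(3)]
        records += [record(f"f{k}", "good", 0.50) for k in range(3)]
        rep = item_film_gating(records)
        assert rep.removed_items == []
        assert rep.flagged_items == ["soso"]

    def test_noise_film_gated(self, make_combo):
        records = []
        for j, film_ok in enumerate([True, True, False]):
            for i in range(4):
                target = 0.5 if film_ok else 0.05
                zs, _ = make_combo(
                    duration_s=200, target_agreement=target, seed=50 + 10 * j + i,
                    film_id=f"f{j}", item_id=f"i{i}",
                )
                records.append(pairwise_agreement(zs))
        rep = item_film_gating(records)
        assert rep.removed_films == ["f2"]

    def test_empty_records_rejected(self):
        from affectconsensus.errors import EmptyInputError

        with pytest.raises(EmptyInputError):
            item_film_gating([])
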