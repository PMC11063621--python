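"""Identification engines: worked example, invariants, oracle agreement."""

import math

import pytest

from conftest import random_dataset
from ericakey.keying import (
    Selection,
    ZeroCarrierWarning,
    compare_taxa,
    format_probability,
    group_contribution,
    probability_rank,
    ranking_population,
    state_carriers,
    strict_match,
    truncate7,
)
from ericakey.matrix_model import DatasetError, KeyDataset, collation_key

# property-suite conditions: seeded random datasets of modest size
PROPERTY_SEEDS = range(40)
PROPERTY_N_TAXA = 60


# ---------------------------------------------------------------------------
# independent brute-force oracle (no calls into the ranking engine)


def brute_force_scores(ds, selection, population="terminal"):
    """Recompute every taxon's score by direct O(taxa x groups) scanning."""
    pop = ranking_population(ds, population)
    scores = {}
    for taxon in pop:
        total = 0.0
        for gid, wanted in selection.constraints.items():
            carriers = [t for t in pop
                        if ds.coding(t.taxon_id, gid) & wanted]
            if carriers and any(t.taxon_id == taxon.taxon_id for t in carriers):
                total += 1.0 / len(carriers)
        scores[taxon.taxon_id] = total
    return scores


def random_selection(ds, rng, max_groups=4):
    """A valid selection over groups that are coded somewhere in ds."""
    groups = list(ds.schema)
    rng.shuffle(groups)
    constraints = {}
    for g in groups[: int(rng.integers(1, max_groups + 1))]:
        k = int(rng.integers(1, min(3, len(g.states)) + 1))
        picks = rng.choice(len(g.states), size=k, replace=False)
        constraints[g.group_id] = [g.states[i] for i in picks]
    return Selection.build(ds.schema, constraints)


# ---------------------------------------------------------------------------
# worked example


class TestWorkedExample:
    def test_tube_carrier_count_and_contribution(self, worked):
        ds, _ = worked
        assert len(state_carriers(ds, "corolla shape", ["tube"])) == 361
        c = group_contribution(ds, "corolla shape", ["tube"])
        assert c.carrier_count == 361
        assert c.display_value == "0.0027700"

    def test_peninsula_carrier_count_and_contribution(self, worked):
        ds, _ = worked
        c = group_contribution(ds, "region", ["Cape Peninsula"])
        assert c.carrier_count == 115
        assert c.display_value == "0.0086956"

    def test_top_scorers_are_the_both_state_taxa_alphabetically(self, worked):
        ds, selection = worked
        ranked = probability_rank(ds, selection)
        top = ranked[:20]
        assert {r.taxon_id for r in top} == {f"amb{i + 1:03d}" for i in range(20)}
        names = [r.name for r in top]
        assert names == sorted(names, key=collation_key)
        assert all(r.score == pytest.approx(1 / 361 + 1 / 115, abs=1e-15)
                   for r in top)
        assert all(r.display_score == "0.0114656" for r in top)

    def test_strict_match_returns_exactly_the_both_state_taxa(self, worked):
        ds, selection = worked
        assert strict_match(ds, selection) == {f"amb{i + 1:03d}"
                                               for i in range(20)}

    def test_breakdown_sums_to_score(self, worked):
        ds, selection = worked
        for r in probability_rank(ds, selection, include_zero=True):
            assert r.score == pytest.approx(sum(r.contributions.values()))
            assert r.matched_groups == sum(
                1 for v in r.contributions.values() if v > 0)


# ---------------------------------------------------------------------------
# display rule


class TestDisplayTruncation:
    @pytest.mark.parametrize("value,shown", [
        (1 / 361, "0.0027700"),   # would round to ...701
        (1 / 115, "0.0086956"),   # would round to ...957
        (1.0, "1.0000000"),
        (0.0, "0.0000000"),
    ])
    def test_probabilities_truncate_not_round(self, value, shown):
        assert format_probability(value) == shown
        assert truncate7(value) == float(shown)


# ---------------------------------------------------------------------------
# single-group and edge behaviour


class TestEdgeCases:
    def test_unique_carrier_gets_full_probability_and_first_rank(self, worked):
        ds, _ = worked
        # give one taxon a coding nobody else has
        ds2 = KeyDataset(schema=ds.schema, taxa=ds.taxa,
                         codings={t: dict(g) for t, g in ds.codings.items()},
                         distributions=ds.distributions, points=ds.points)
        ds2.codings["amb001"]["resprouting"] = frozenset({"resprouter"})
        c = group_contribution(ds2, "resprouting", ["resprouter"])
        assert c.value == 1.0
        selection = Selection.build(ds.schema, {"resprouting": ["resprouter"]})
        ranked = probability_rank(ds2, selection)
        assert ranked[0].taxon_id == "amb001" and ranked[0].score == 1.0
        assert len(ranked) == 1

    def test_zero_carrier_group_contributes_zero_with_warning(self, worked):
        ds, _ = worked
        with pytest.warns(ZeroCarrierWarning, match="resprouting"):
            c = group_contribution(ds, "resprouting", ["resprouter"])
        assert c.value == 0.0 and c.carrier_count == 0
        sel = Selection.build(ds.schema, {"corolla shape": ["tube"],
                                          "resprouting": ["resprouter"]})
        with pytest.warns(ZeroCarrierWarning):
            ranked = probability_rank(ds, sel)
        assert len(ranked) == 361  # tube carriers still ranked
        assert strict_match(ds, sel) == set()

    def test_empty_selection_is_rejected(self, worked):
        ds, _ = worked
        with pytest.raises(DatasetError, match="at least one group"):
            Selection(constraints={})

    def test_unknown_state_is_an_error_naming_the_token(self, worked):
        ds, _ = worked
        with pytest.raises(DatasetError, match="tubee"):
            state_carriers(ds, "corolla shape", ["tubee"])

    def test_identical_codings_tie_and_sort_alphabetically(self, worked):
        ds, selection = worked
        ranked = probability_rank(ds, selection)
        scores = [r.score for r in ranked]
        assert scores == sorted(scores, reverse=True)
        for a, b in zip(ranked, ranked[1:]):
            if a.score == b.score:
                assert collation_key(a.name) <= collation_key(b.name)

    def test_full_vocabulary_selection_carries_every_coded_taxon(self, worked):
        ds, _ = worked
        group = ds.schema.group("corolla shape")
        carriers = state_carriers(ds, "corolla shape", group.states)
        coded = {t.taxon_id for t in ds.terminal_taxa()
                 if ds.coding(t.taxon_id, "corolla_shape")}
        assert carriers == coded


# ---------------------------------------------------------------------------
# missing-data behaviour (probability mode degrades, strict mode eliminates)


class TestMissingData:
    def test_blanked_group_drops_strict_but_only_reduces_rank(self, worked):
        ds, selection = worked
        target = "amb001"
        blanked = KeyDataset(schema=ds.schema, taxa=ds.taxa,
                             codings={t: dict(g) for t, g in ds.codings.items()},
                             distributions=ds.distributions, points=ds.points)
        del blanked.codings[target]["region"]

        assert target in strict_match(ds, selection)
        assert target not in strict_match(blanked, selection)

        before = {r.taxon_id: r for r in probability_rank(ds, selection)}
        after = {r.taxon_id: r for r in probability_rank(blanked, selection)}
        assert target in after
        # the target forfeits exactly the contribution it used to earn
        lost = before[target].contributions["region"]
        assert lost == pytest.approx(1 / 115, abs=1e-15)
        assert after[target].score == pytest.approx(
            before[target].score - lost, abs=1e-12)
        assert after[target].contributions["region"] == 0.0


# ---------------------------------------------------------------------------
# invariants over random datasets


class TestRankingProperties:
    @pytest.mark.parametrize("seed", PROPERTY_SEEDS)
    def test_normalization_contributions_sum_to_one(self, seed):
        import numpy as np
        ds = random_dataset(seed, n_taxa=PROPERTY_N_TAXA)
        rng = np.random.default_rng(seed + 1000)
        sel = random_selection(ds, rng, max_groups=1)
        (gid, states), = sel.constraints.items()
        carriers = state_carriers(ds, gid, states)
        if not carriers:
            return
        c = group_contribution(ds, gid, states)
        assert len(carriers) * c.value == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", PROPERTY_SEEDS)
    def test_uncertainty_monotonicity_more_states_never_raise_value(self, seed):
        import numpy as np
        ds = random_dataset(seed, n_taxa=PROPERTY_N_TAXA)
        rng = np.random.default_rng(seed + 2000)
        group = ds.schema.groups[int(rng.integers(len(ds.schema)))]
        states = list(group.states)
        rng.shuffle(states)
        prev_value = None
        for k in range(1, len(states) + 1):
            carriers = state_carriers(ds, group.group_id, states[:k])
            value = 1.0 / len(carriers) if carriers else 0.0
            if prev_value is not None and prev_value > 0 and value > 0:
                assert value <= prev_value + 1e-15
            if value > 0:
                prev_value = value

    def test_rarity_reward_rarer_state_contributes_more(self, worked):
        ds, _ = worked
        rare = group_contribution(ds, "region", ["Cape Peninsula"])   # 115
        common = group_contribution(ds, "corolla shape", ["tube"])    # 361
        assert rare.carrier_count < common.carrier_count
        assert rare.value > common.value

    @pytest.mark.parametrize("seed", PROPERTY_SEEDS)
    def test_strict_match_equals_argmax_of_probability(self, seed):
        import numpy as np
        ds = random_dataset(seed, n_taxa=PROPERTY_N_TAXA)
        rng = np.random.default_rng(seed + 3000)
        sel = random_selection(ds, rng)
        strict = strict_match(ds, sel)
        if not strict:
            return
        max_possible = 0.0
        for gid, states in sel.constraints.items():
            carriers = state_carriers(ds, gid, states)
            if carriers:
                max_possible += 1.0 / len(carriers)
        scores = brute_force_scores(ds, sel)
        argmax = {t for t, s in scores.items()
                  if math.isclose(s, max_possible, rel_tol=0, abs_tol=1e-12)}
        assert strict == argmax

    @pytest.mark.parametrize("seed", PROPERTY_SEEDS)
    def test_engine_agrees_with_brute_force_oracle(self, seed):
        import numpy as np
        ds = random_dataset(seed, n_taxa=PROPERTY_N_TAXA)
        rng = np.random.default_rng(seed + 4000)
        sel = random_selection(ds, rng)
        expected = brute_force_scores(ds, sel)
        ranked = probability_rank(ds, sel, include_zero=True)
        assert {r.taxon_id for r in ranked} == set(expected)
        for r in ranked:
            assert r.score == pytest.approx(expected[r.taxon_id], abs=1e-12)
        order = [(r.taxon_id, r.name) for r in ranked]
        resorted = sorted(order, key=lambda pair: (-expected[pair[0]],
                                                   collation_key(pair[1])))
        assert order == resorted


# ---------------------------------------------------------------------------
# comparison


class TestCompare:
    def test_only_differing_row_is_corolla_colour(self, tiny_dataset):
        table = compare_taxa(tiny_dataset, ["pl-h", "Erica arborea"],
                             ["corolla shape", "corolla colour"])
        assert table.differing_rows() == ["corolla_colour"]

    def test_missing_coding_is_distinct_from_states(self, tiny_dataset):
        table = compare_taxa(tiny_dataset, ["ar", "pl"])
        row = dict(table.rows)["corolla_shape"]
        assert row == (frozenset({"tube"}), None)

    def test_restricted_single_group_table(self, tiny_dataset):
        table = compare_taxa(tiny_dataset, ["ar", "pl-h", "pl-p"],
                             ["flowering month"])
        assert len(table.rows) == 1 and len(table.taxa) == 3

    def test_self_comparison_rejected(self, tiny_dataset):
        with pytest.raises(DatasetError, match="duplicate"):
            compare_taxa(tiny_dataset, ["ar", "ar"])

    def test_fewer_than_two_taxa_rejected(self, tiny_dataset):
        with pytest.raises(DatasetError, match="two"):
            compare_taxa(tiny_dataset, ["ar"])

    def test_rows_follow_schema_order(self, tiny_dataset):
        table = compare_taxa(tiny_dataset, ["ar", "pl-h"])
        assert [gid for gid, _ in table.rows] == list(
            tiny_dataset.schema.group_ids)
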