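"""Rule extraction: expansion, graph combination, SMIRKS, genericity."""

import math

import pytest

from envirule.chem import parse_reaction
from envirule.cluster import cluster
from envirule.fingerprints import detect_reaction_center
from envirule.rules import (
    build_composite_rule,
    build_observed_index,
    combine,
    compute_genericity,
    expand_center,
    generate_ruleset,
    optimal_combination_size,
    saturation_diameter,
    tune_genericity,
)
from envirule.synthetic import build_reaction, genericity_ladder_fixture


def _ester_group(pairs, d):
    """Cluster ester hydrolyses with (acyl R1, alkyl R2) substituents."""
    rxns = [
        build_reaction("ester_hydrolysis", f"{r1}C(=O)O{r2}", f"e{i}")
        for i, (r1, r2) in enumerate(pairs)
    ]
    (group,) = cluster(rxns)
    return group


class TestExpandCenter:
    def test_zero_diameter_is_the_bare_center(self):
        r = build_reaction("dechlorination", "CCCCl", "r")
        g = expand_center(r, detect_reaction_center(r), 0)
        assert all(opt == (None, None) for opt in g.profiles["r"])

    def test_saturating_diameter_covers_whole_substrate(self):
        r = build_reaction("dechlorination", "CCCCl", "r")
        (grp,) = cluster([r])
        d_sat = saturation_diameter(grp)
        g_sat = expand_center(r, detect_reaction_center(r), d_sat)
        g_more = expand_center(r, detect_reaction_center(r), d_sat + 3)
        # beyond saturation nothing changes except frontier relaxation
        assert d_sat == 2
        env_sat = [e for e, _ in g_sat.profiles["r"] if e]
        assert env_sat  # the whole propyl chain is in the environment

    def test_diameter_one_sees_only_immediate_neighbors(self):
        r = build_reaction("alcohol_oxidation", "CC(O)c1ccccc1", "r", strict=True)
        g1 = expand_center(r, detect_reaction_center(r), 1)
        envs = [e for e, _ in g1.profiles["r"] if e]
        # benzylic center at d=1: the ipso aromatic carbon appears, the
        # rest of the ring does not
        assert any("[c]" in e for e in envs)
        assert all(e.count("[c]") <= 1 for e in envs)


class TestCombine:
    # diameter 3 makes both attachment atoms of the ester center see their
    # substituents, so the four classic two-reaction combination cases are
    # exercised faithfully

    def test_equal_substituent_sets_merge_to_one(self):
        group = _ester_group([("CCC", "CCC"), ("CCCC", "CCCC")], d=3)
        rule = build_composite_rule(group, 3, 0)
        assert len(rule.simple_rules) == 1

    def test_one_side_varying_merges_to_one(self):
        # one attachment atom shared, the other differing (both orders)
        for pairs in (
            [("CCC", "CCC"), ("CCC", "COC")],
            [("CCC", "CCC"), ("COC", "CCC")],
        ):
            group = _ester_group(pairs, d=3)
            rule = build_composite_rule(group, 3, 0)
            assert len(rule.simple_rules) == 1

    def test_unobserved_cross_combination_blocks_merging(self):
        # both positions differ and the cross pairings were never seen:
        # the two reactions cannot share one simple rule
        group = _ester_group([("CCC", "CCC"), ("COC", "COC")], d=3)
        rule = build_composite_rule(group, 3, 0)
        assert len(rule.simple_rules) == 2

    def test_single_graph_returned_unchanged(self):
        r = build_reaction("dechlorination", "CCCCl", "r")
        g = expand_center(r, detect_reaction_center(r), 2)
        assert combine([g]) == [g]

    def test_zero_diameter_always_merges_everything(self):
        group = _ester_group(
            [("CCC", "CCC"), ("COC", "COC"), ("CCCC", "CC(C)C")], d=0
        )
        rule = build_composite_rule(group, 0, 0)
        assert len(rule.simple_rules) == 1

    @pytest.mark.parametrize(
        "pairs",
        [
            [("CCC", "CCC"), ("COC", "COC"), ("CCC", "COC")],
            [("CCC", "CCC"), ("COC", "CCC"), ("CC(C)C", "CCC"),
             ("CCC", "COC"), ("COC", "COC")],
            [("CCC", "CCC"), ("COC", "COC"), ("CC(C)C", "CC(C)C"),
             ("CCC", "COC")],
        ],
    )
    def test_greedy_merge_count_is_optimal(self, pairs):
        from envirule.rules import aligned_substrate_graphs

        group = _ester_group(pairs, d=3)
        greedy_rule = build_composite_rule(group, 3, 0)
        _, _, graphs = aligned_substrate_graphs(group.members, 3, 0)
        assert len(greedy_rule.simple_rules) == optimal_combination_size(graphs)


class TestEmit:
    def test_rule_reproduces_every_source_reaction(self, corpus_groups, fgs):
        for group in corpus_groups:
            rule = build_composite_rule(group, 1, 0, fgs)
            for member in group.members:
                assert rule.covers(member)

    def test_max_diameter_rule_matches_only_its_own_substrates(self):
        rxns = [build_reaction("dechlorination", s, f"r{i}")
                for i, s in enumerate(["CCCCl", "CC(C)CCl"])]
        (group,) = cluster(rxns)
        d_sat = saturation_diameter(group)
        rule = build_composite_rule(group, d_sat, d_sat + 1)
        assert rule.triggers("CCCCl")
        assert not rule.triggers("CCCCCl")
        assert not rule.triggers("ClCCCO")

    def test_nitro_rule_generalizes_at_diameter_zero(self):
        rxns = [build_reaction("nitro_reduction", s, f"n{i}")
                for i, s in enumerate(
                    ["CCC[N+](=O)[O-]", "CCCC[N+](=O)[O-]",
                     "CC(C)C[N+](=O)[O-]"])]
        (group,) = cluster(rxns)
        rule = build_composite_rule(group, 0, 0)
        for r in rxns:
            assert rule.covers(r)
        # converts a nitro on an unseen carbon skeleton too
        assert rule.apply("CCCCCC[N+](=O)[O-]") == frozenset(
            {frozenset({"CCCCCCN"})}
        )


class TestSpecificityMonotonicity:
    def test_trigger_sets_shrink_with_diameter_and_hydrogens(self, corpus,
                                                             corpus_groups,
                                                             fgs):
        compounds = corpus.compounds
        for group in corpus_groups:
            prev = None
            for d in range(0, 3):
                rule = build_composite_rule(group, d, 0, fgs)
                trig = {c for c in compounds if rule.triggers(c)}
                if prev is not None:
                    assert trig <= prev
                prev = trig
            rule_h = build_composite_rule(group, 2, 1, fgs)
            trig_h = {c for c in compounds if rule_h.triggers(c)}
            assert trig_h <= prev


class TestGenericity:
    def test_direct_ratio(self, corpus_ruleset, corpus):
        # a rule firing on 10 compounds with 2 observed matches has
        # genericity (10 - 2) / 2
        rule = corpus_ruleset.rule_list[0]
        observed = corpus.observed()
        subs = [s for s in corpus.compounds if rule.triggers(s)]
        matched = [
            s
            for s in subs
            if any(o in observed.get(s, ()) for o in rule.apply(s))
        ]
        ns, ps = len(subs) - len(matched), len(matched)
        assert compute_genericity(rule, corpus.compounds, observed) == ns / ps

    def test_zero_when_all_triggers_are_observed(self, corpus_ruleset, corpus):
        for rule in corpus_ruleset.rule_list:
            assert compute_genericity(
                rule, corpus.compounds, corpus.observed()
            ) == 0.0

    def test_infinite_when_no_trigger_is_observed(self):
        rxns = [build_reaction("dechlorination", s, f"r{i}")
                for i, s in enumerate(["CCCCl", "CCCCCl"])]
        (group,) = cluster(rxns)
        rule = build_composite_rule(group, 0, 0)
        g = compute_genericity(rule, ["CCCCCCCl"], {})
        assert math.isinf(g)

    def test_undefined_when_rule_never_fires(self):
        rxns = [build_reaction("dechlorination", s, f"r{i}")
                for i, s in enumerate(["CCCCl", "CCCCCl"])]
        (group,) = cluster(rxns)
        rule = build_composite_rule(group, 0, 0)
        assert compute_genericity(rule, ["CCO", "CCN"], {}) is None


class TestTuneGenericity:
    def test_ladder_selects_the_closest_state(self):
        # engineered so diameters 0/1/2 give genericities 8.0/4.0/1.0;
        # target 5 must select diameter 1 (|4-5| < |8-5|)
        rxns, compounds, observed = genericity_ladder_fixture()
        (group,) = cluster(rxns)
        gs = {
            d: compute_genericity(
                build_composite_rule(group, d, 0), compounds, observed
            )
            for d in (0, 1, 2)
        }
        assert gs == {0: 8.0, 1: 4.0, 2: 1.0}
        rule = tune_genericity(group, 5.0, compounds, observed)
        assert (rule.diameter, rule.h_level) == (1, 0)
        assert rule.genericity == 4.0

    def test_target_zero_reaches_the_most_specific_covering_state(self):
        rxns, compounds, observed = genericity_ladder_fixture()
        (group,) = cluster(rxns)
        rule = tune_genericity(group, 0.0, compounds, observed)
        # explicit-H constraints exclude the last surviving decoys while
        # the members stay covered
        assert rule.genericity == 0.0
        assert rule.h_level >= 1
        for r in rxns:
            assert rule.covers(r)

    def test_huge_target_stays_fully_generic(self):
        rxns, compounds, observed = genericity_ladder_fixture()
        (group,) = cluster(rxns)
        rule = tune_genericity(group, 1e9, compounds, observed)
        assert (rule.diameter, rule.h_level) == (0, 0)

    def test_tuned_rule_always_covers_the_group(self, corpus, corpus_groups,
                                                fgs):
        observed = corpus.observed()
        for group in corpus_groups:
            for target in (0.0, 5.0):
                rule = tune_genericity(
                    group, target, corpus.compounds, observed, fgs
                )
                for member in group.members:
                    assert rule.covers(member)


class TestGenerateRuleset:
    def test_no_eligible_groups_gives_empty_ruleset(self):
        r = build_reaction("dechlorination", "CCCCl", "solo")
        groups = cluster([r])
        rs = generate_ruleset(groups, 5.0, ["CCCCl"], build_observed_index([r]))
        assert rs.rules == {}
        assert len(rs.groups) == 1  # singleton fingerprint still stored

    def test_one_rule_per_eligible_group(self, corpus_ruleset, corpus_groups):
        eligible = [g.group_id for g in corpus_groups if g.eligible]
        assert sorted(corpus_ruleset.rules) == sorted(eligible)

    def test_primary_and_secondary_alcohols_share_one_composite_rule(self):
        rxns = [build_reaction("alcohol_oxidation", s, f"s{i}")
                for i, s in enumerate(["CCC(O)CC", "CC(O)CC"])]
        rxns += [build_reaction("alcohol_oxidation_primary", s, f"p{i}")
                 for i, s in enumerate(["CCCO", "CCCCO"])]
        groups = cluster(rxns)
        assert len(groups) == 1
        rs = generate_ruleset(
            groups,
            5.0,
            sorted({r.substrate_smiles for r in rxns}),
            build_observed_index(rxns),
        )
        (rule,) = rs.rule_list
        for r in rxns:
            assert rule.covers(r)
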