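"""Incremental rule-set updating and reaction coverage."""

import numpy as np
import pytest

from envirule.adder import add_reactions, coverage
from envirule.cluster import cluster
from envirule.rules import RuleSet, build_observed_index, generate_ruleset
from envirule.synthetic import build_reaction, make_corpus


def _make_ruleset(reactions, fgs, target=5.0, extra_compounds=()):
    observed = build_observed_index(reactions)
    compounds = sorted(
        {r.substrate_smiles for r in reactions} | set(extra_compounds)
    )
    groups = cluster(reactions, fgs)
    return generate_ruleset(groups, target, compounds, observed, fgs)


def _update(ruleset, new, fgs):
    all_rxns = [m for g in ruleset.groups for m in g.members] + list(new)
    compounds = sorted({r.substrate_smiles for r in all_rxns})
    return add_reactions(
        ruleset, new, compounds, build_observed_index(all_rxns)
    )


class TestAddReactions:
    def test_fingerprint_match_extends_the_group(self, fgs):
        base = [build_reaction("dechlorination", s, f"r{i}")
                for i, s in enumerate(["CCCCl", "CCCCCl"])]
        rs = _make_ruleset(base, fgs)
        new = [build_reaction("dechlorination", "CCCCCCl", "new1")]
        report = _update(rs, new, fgs)
        assert report.reactions_added == 1
        assert not report.rules_created
        (group,) = [g for g in rs.groups if "new1" in g.member_ids]
        assert len(group.members) == 3

    def test_novel_center_founds_an_ineligible_singleton(self, fgs):
        base = [build_reaction("dechlorination", s, f"r{i}")
                for i, s in enumerate(["CCCCl", "CCCCCl"])]
        rs = _make_ruleset(base, fgs)
        new = [build_reaction("nitro_reduction", "CCC[N+](=O)[O-]", "n1")]
        report = _update(rs, new, fgs)
        assert report.groups_created
        assert not report.rules_created  # singleton: no rule yet
        assert len(rs.rules) == 1

    def test_second_member_makes_a_stored_singleton_eligible(self, fgs):
        base = [build_reaction("dechlorination", s, f"r{i}")
                for i, s in enumerate(["CCCCl", "CCCCCl"])]
        base.append(build_reaction("nitro_reduction", "CCC[N+](=O)[O-]", "n1"))
        rs = _make_ruleset(base, fgs)
        assert len(rs.rules) == 1
        new = [build_reaction("nitro_reduction", "CCCC[N+](=O)[O-]", "n2")]
        report = _update(rs, new, fgs)
        assert report.groups_newly_eligible
        assert report.rules_created
        assert len(rs.rules) == 2

    def test_new_substituent_widens_the_rule(self, fgs):
        # a known center with an unseen neighboring group: the composite
        # rule gains that substituent option
        base = [build_reaction("dechlorination", s, f"r{i}")
                for i, s in enumerate(["CCCCl", "CCCCCl"])]
        rs = _make_ruleset(base, fgs, target=0.0)
        new = [build_reaction("dechlorination", "CC(C)C(C)CCl", "new1")]
        before = rs.rule_list[0].smirks_list
        report = _update(rs, new, fgs)
        after = rs.rule_list[0].smirks_list
        assert report.rules_changed
        assert before != after
        covered, uncovered = coverage(
            rs, [m for g in rs.groups for m in g.members]
        )
        assert not uncovered

    def test_unmappable_reactions_are_skipped_and_counted(self, fgs):
        from envirule.chem import parse_reaction

        base = [build_reaction("dechlorination", s, f"r{i}")
                for i, s in enumerate(["CCCCl", "CCCCCl"])]
        rs = _make_ruleset(base, fgs)
        bad = parse_reaction("c1ccccc1CCCCCCCC>>c1ccccc1CCCCCCCN", "bad")
        report = _update(rs, [bad], fgs)
        assert report.reactions_skipped == ["bad"]
        assert report.reactions_added == 0


class TestCoverage:
    def test_empty_ruleset_covers_nothing(self, corpus):
        rs = RuleSet(groups=[], rules={}, target_genericity=5.0)
        covered, uncovered = coverage(rs, corpus.reactions)
        assert not covered
        assert len(uncovered) == len(corpus.reactions)

    def test_ruleset_covers_its_own_training_reactions(self, corpus,
                                                       corpus_ruleset):
        covered, uncovered = coverage(corpus_ruleset, corpus.reactions)
        assert not uncovered

    def test_only_the_novel_singleton_stays_uncovered(self, fgs):
        old = [build_reaction("dechlorination", s, f"r{i}")
               for i, s in enumerate(
                   ["CCCCl", "CCCCCl", "CCCCCCl", "CC(C)CCl", "CCCCCCCl"])]
        rs = _make_ruleset(old, fgs)
        new = [
            build_reaction("dechlorination", "CCC(C)CCl", "new1"),
            build_reaction("dechlorination", "CCCC(C)CCl", "new2"),
            build_reaction("nitro_reduction", "CCC[N+](=O)[O-]", "new3"),
        ]
        _update(rs, new, fgs)
        covered, uncovered = coverage(
            rs, [m for g in rs.groups for m in g.members]
        )
        assert [r.reaction_id for r in uncovered] == ["new3"]

    def test_covered_set_never_shrinks_after_update(self, fgs):
        corpus = make_corpus(n_per_family=5, seed=4)
        reactions = corpus.reactions
        rs = _make_ruleset(reactions[:12], fgs)
        before, _ = coverage(rs, reactions)
        _update(rs, reactions[12:], fgs)
        after, _ = coverage(rs, reactions)
        assert {r.reaction_id for r in before} <= {r.reaction_id for r in after}


class TestIncrementalEquivalence:
    def _partition(self, groups):
        return {frozenset(g.member_ids) for g in groups}

    def _trigger_profile(self, ruleset, compounds):
        """member-set -> set of compounds its rule fires on."""
        out = {}
        for g in ruleset.groups:
            if g.group_id in ruleset.rules:
                rule = ruleset.rules[g.group_id]
                out[frozenset(g.member_ids)] = {
                    c for c in compounds if rule.triggers(c)
                }
        return out

    @pytest.mark.parametrize("split_seed", [0, 1])
    def test_incremental_equals_batch(self, fgs, split_seed):
        corpus = make_corpus(n_per_family=5, seed=4)
        reactions = corpus.reactions
        rng = np.random.default_rng(split_seed)
        mask = rng.random(len(reactions)) < 0.6
        part_a = [r for r, m in zip(reactions, mask) if m]
        part_b = [r for r, m in zip(reactions, mask) if not m]
        compounds = sorted({r.substrate_smiles for r in reactions})
        observed = build_observed_index(reactions)

        incremental = generate_ruleset(
            cluster(part_a, fgs), 5.0, compounds, observed, fgs
        )
        add_reactions(incremental, part_b, compounds, observed)
        batch = generate_ruleset(
            cluster(reactions, fgs), 5.0, compounds, observed, fgs
        )
        assert self._partition(incremental.groups) == self._partition(batch.groups)
        assert self._trigger_profile(incremental, compounds) == (
            self._trigger_profile(batch, compounds)
        )

    def test_untouched_rules_are_byte_identical(self, fgs):
        base = [build_reaction("dechlorination", s, f"r{i}")
                for i, s in enumerate(["CCCCl", "CCCCCl"])]
        base += [build_reaction("alcohol_oxidation", s, f"o{i}")
                 for i, s in enumerate(["CCC(O)CC", "CC(O)CC"])]
        rs = _make_ruleset(base, fgs)
        untouched_id = [
            g.group_id for g in rs.groups if "o0" in g.member_ids
        ][0]
        before = list(rs.rules[untouched_id].smirks_list)
        before_obj = rs.rules[untouched_id]
        _update(rs, [build_reaction("dechlorination", "CCCCCCl", "n")], fgs)
        assert rs.rules[untouched_id] is before_obj
        assert rs.rules[untouched_id].smirks_list == before
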