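"""Incremental updating of a persisted rule set with new reactions.

A new reaction joins the stored group whose fingerprint it matches at
Tanimoto 1.0 (exact descriptor-multiset equality); otherwise it founds a
new group.  Only touched groups have their rules regenerated, re-tuned to
the rule set's stored target genericity; untouched groups' rules are left
byte-identical.  Because singleton groups keep their fingerprints, an
incremental update is equivalent to re-clustering the combined reaction
set from scratch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chem import MappedReaction
from .cluster import ReactionGroup
from .fingerprints import fingerprint_reaction
from .rules import RuleSet, tune_genericity

logger = logging.getLogger(__name__)


@dataclass
class UpdateReport:
    rules_changed: list = field(default_factory=list)
    rules_created: list = field(default_factory=list)
    groups_newly_eligible: list = field(default_factory=list)
    groups_created: list = field(default_factory=list)
    reactions_added: int = 0
    reactions_skipped: list = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "rules_changed": self.rules_changed,
            "rules_created": self.rules_created,
            "groups_newly_eligible": self.groups_newly_eligible,
            "groups_created": self.groups_created,
            "reactions_added": self.reactions_added,
            "reactions_skipped": self.reactions_skipped,
        }


def add_reactions(
    ruleset: RuleSet,
    new_reactions: Sequence,
    compounds: Sequence[str],
    observed: Mapping[str, set],
) -> UpdateReport:
    """Extend matching groups, create new ones, regenerate touched rules.

    Mutates ``ruleset`` in place and returns an :class:`UpdateReport`.
    Unmappable reactions are skipped with a logged warning.
    """
    from .chem import ensure_mapped

    report = UpdateReport()
    existing_ids = {m.reaction_id for g in ruleset.groups for m in g.members}
    by_key = {g.fingerprint.key(): g for g in ruleset.groups}
    touched: dict = {}
    next_index = len(ruleset.groups)

    for reaction in new_reactions:
        try:
            mapped = ensure_mapped(reaction)
        except Exception as exc:
            logger.warning(
                "skipping unmappable reaction %r: %s",
                getattr(reaction, "reaction_id", "?"),
                exc,
            )
            report.reactions_skipped.append(getattr(reaction, "reaction_id", "?"))
            continue
        if mapped.reaction_id in existing_ids:
            raise ValueError(f"duplicate reaction id {mapped.reaction_id!r}")
        existing_ids.add(mapped.reaction_id)

        fp = fingerprint_reaction(mapped, ruleset.functional_groups)
        key = fp.key()
        group = by_key.get(key)
        if group is None:
            next_index += 1
            group = ReactionGroup(
                group_id=f"group-{next_index:04d}", fingerprint=fp, members=[]
            )
            by_key[key] = group
            ruleset.groups.append(group)
            report.groups_created.append(group.group_id)
        was_eligible = group.eligible
        group.members.append(mapped)
        group.members.sort(key=lambda m: m.reaction_id)
        report.reactions_added += 1
        if group.eligible and not was_eligible:
            report.groups_newly_eligible.append(group.group_id)
        touched[group.group_id] = group

    for group_id, group in sorted(touched.items()):
        if not group.eligible:
            continue
        had_rule = group_id in ruleset.rules
        old = ruleset.rules.get(group_id)
        rule = tune_genericity(
            group,
            ruleset.target_genericity,
            compounds,
            observed,
            ruleset.functional_groups,
            ruleset.max_diameter,
        )
        ruleset.rules[group_id] = rule
        if not had_rule:
            report.rules_created.append(group_id)
        elif old.smirks_list != rule.smirks_list or (
            old.diameter,
            old.h_level,
        ) != (rule.diameter, rule.h_level):
            report.rules_changed.append(group_id)
    return report


def coverage(ruleset: RuleSet, reactions: Sequence[MappedReaction]):
    """Partition reactions into (covered, uncovered).

    A reaction is covered iff some composite rule applied to its substrate
    reproduces the observed product set.
    """
    covered, uncovered = [], []
    for r in reactions:
        if any(rule.covers(r) for rule in ruleset.rule_list):
            covered.append(r)
        else:
            uncovered.append(r)
    return covered, uncovered
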