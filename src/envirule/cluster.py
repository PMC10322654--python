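"""Partition reactions into groups of identical reaction fingerprints.

Two reactions share a group iff their fingerprints have Tanimoto similarity
exactly 1.0, i.e. all three descriptor multisets are equal.  Multiset
equality is an equivalence relation, so the partition is well defined and
independent of input order.  Singleton groups are retained (their
fingerprints are stored so the reaction adder can later make them eligible)
but only groups with at least two members are sent to the rule generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .chem import MappedReaction
from .fingerprints import FunctionalGroup, ReactionFingerprint, fingerprint_reaction


class DuplicateReactionIdError(ValueError):
    pass


@dataclass
class ReactionGroup:
    group_id: str
    fingerprint: ReactionFingerprint
    members: list  # of MappedReaction

    @property
    def member_ids(self) -> list:
        return [m.reaction_id for m in self.members]

    @property
    def eligible(self) -> bool:
        return len(self.members) >= 2


def cluster(
    reactions: Sequence[MappedReaction],
    functional_groups: Sequence[FunctionalGroup] = (),
) -> list:
    """Group reactions by exact fingerprint equality.

    Groups are ordered (and numbered) by their lexicographically smallest
    member reaction-id, so the output is invariant under permutation of the
    input.
    """
    seen = set()
    for r in reactions:
        if r.reaction_id in seen:
            raise DuplicateReactionIdError(
                f"duplicate reaction id {r.reaction_id!r}"
            )
        seen.add(r.reaction_id)

    by_key: dict = {}
    for r in reactions:
        fp = fingerprint_reaction(r, functional_groups)
        by_key.setdefault(fp.key(), (fp, []))[1].append(r)

    buckets = sorted(
        by_key.values(), key=lambda fr: min(m.reaction_id for m in fr[1])
    )
    groups = []
    for i, (fp, members) in enumerate(buckets):
        members = sorted(members, key=lambda m: m.reaction_id)
        groups.append(
            ReactionGroup(group_id=f"group-{i + 1:04d}", fingerprint=fp, members=members)
        )
    return groups
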