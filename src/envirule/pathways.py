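"""Directed pathway graphs of compounds connected by reactions.

Nodes are canonical compound SMILES; edges carry the reaction that turns a
parent into one of its children.  The generation of a node is its shortest
edge-distance from a root (entry compound); multi-generation evaluation
discounts deeper generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .chem import canonical_smiles, parse_reaction


class PathwayCycleError(ValueError):
    pass


@dataclass
class PathwayGraph:
    pathway_id: str
    graph: nx.DiGraph  # nodes: canonical SMILES; edge attr "reaction_id"
    reactions: dict = field(default_factory=dict)  # reaction_id -> MappedReaction

    @classmethod
    def from_edges(cls, pathway_id: str, edges: Sequence, cosub=None) -> "PathwayGraph":
        """Build from (parent_smiles, reaction_smiles, children_smiles) triples."""
        from .chem import DEFAULT_COSUBSTRATES

        cosub = cosub or DEFAULT_COSUBSTRATES
        g = nx.DiGraph()
        reactions = {}
        for i, (parent, rxn_smiles, children) in enumerate(edges):
            rid = f"{pathway_id}-e{i}"
            reaction = parse_reaction(rxn_smiles, rid, cosub)
            reactions[rid] = reaction
            p = canonical_smiles(parent)
            g.add_node(p)
            for child in children:
                c = canonical_smiles(child)
                g.add_edge(p, c, reaction_id=rid)
        pw = cls(pathway_id=pathway_id, graph=g, reactions=reactions)
        pw.validate()
        return pw

    def validate(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise PathwayCycleError(
                f"pathway {self.pathway_id!r} contains a cycle after "
                "canonical-form collapsing"
            )
        roots = self.roots
        reachable = set(roots)
        for r in roots:
            reachable |= nx.descendants(self.graph, r)
        missing = set(self.graph.nodes) - reachable
        if missing:
            raise ValueError(
                f"pathway {self.pathway_id!r}: nodes unreachable from any "
                f"root: {sorted(missing)}"
            )

    @property
    def roots(self) -> list:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    def generations(self) -> dict:
        """node -> shortest edge-distance from the nearest root."""
        gen: dict = {}
        for root in self.roots:
            for node, depth in nx.single_source_shortest_path_length(
                self.graph, root
            ).items():
                if node not in gen or depth < gen[node]:
                    gen[node] = depth
        return gen

    @property
    def max_generation(self) -> int:
        gens = self.generations()
        return max(gens.values()) if gens else 0

    def all_reactions(self) -> list:
        return [self.reactions[k] for k in sorted(self.reactions)]

    def to_json(self) -> dict:
        edges = []
        for parent, child, data in sorted(self.graph.edges(data=True)):
            rid = data["reaction_id"]
            edges.append(
                {
                    "parent-smiles": parent,
                    "reaction-smiles": self.reactions[rid].smiles()
                    if hasattr(self.reactions[rid], "smiles")
                    else self.reactions[rid],
                    "children-smiles": [child],
                }
            )
        return {"pathway-id": self.pathway_id, "edges": edges}

    @classmethod
    def from_json(cls, data: Mapping) -> "PathwayGraph":
        edges = [
            (e["parent-smiles"], e["reaction-smiles"], e["children-smiles"])
            for e in data["edges"]
        ]
        return cls.from_edges(data["pathway-id"], edges)
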