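"""File formats: reaction lists, pathways, functional groups, rule sets.

* Reaction file — UTF-8 text, one reaction SMILES per line, ``#`` comments;
  an optional tab-separated column carries the reaction id (either order).
* Pathway file — JSON: ``{"pathway-id": ..., "edges": [{"parent-smiles",
  "reaction-smiles", "children-smiles"}]}`` or a list of such objects.
* Functional-group file — YAML list of ``{name, smarts}``.
* Rule set — JSON embedding SMIRKS strings, group fingerprints, member
  reactions, diameters and genericity values.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .chem import CosubstrateConfig, DEFAULT_COSUBSTRATES, parse_reaction
from .cluster import ReactionGroup
from .fingerprints import FunctionalGroup, ReactionFingerprint
from .pathways import PathwayGraph
from .rules import CompositeRule, RuleSet, SimpleRule


def read_reaction_file(path, cosub: CosubstrateConfig = DEFAULT_COSUBSTRATES):
    """Parse a reaction file into (possibly unmapped) reaction objects."""
    reactions = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        rid = ""
        if "\t" in line:
            a, b = line.split("\t", 1)
            smiles, rid = (a, b) if ">>" in a else (b, a)
            smiles, rid = smiles.strip(), rid.strip()
        else:
            smiles = line
        if not rid:
            rid = f"line-{lineno}"
        try:
            reactions.append(parse_reaction(smiles, rid, cosub))
        except Exception as exc:
            raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return reactions


def write_reaction_file(path, reactions):
    lines = [f"{r.smiles()}\t{r.reaction_id}" for r in reactions]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pathway_file(path) -> list:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [PathwayGraph.from_json(d) for d in data]


def write_pathway_file(path, pathways: Sequence[PathwayGraph]):
    Path(path).write_text(
        json.dumps([p.to_json() for p in pathways], indent=1) + "\n"
    )


def read_functional_groups(path=None) -> list:
    """Load functional-group SMARTS; defaults to the bundled library."""
    if path is None:
        text = (
            resources.files("envirule") / "data" / "functional_groups.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    entries = yaml.safe_load(text) or []
    return [FunctionalGroup(e["name"], e["smarts"]) for e in entries]


def read_rule_file(path) -> list:
    """Plain-text one-SMARTS/SMIRKS-per-line rule file (external rule sets)."""
    rules = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            rules.append(line)
    return rules


def export_smirks(path, ruleset: RuleSet):
    """One simple-rule SMIRKS per line, for interoperability."""
    lines = []
    for rule in ruleset.rule_list:
        for simple in rule.simple_rules:
            lines.append(simple.smirks)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# rule-set JSON persistence
# ---------------------------------------------------------------------------


def _genericity_to_json(g):
    if g is None:
        return None
    if math.isinf(g):
        return "inf"
    return g


def _genericity_from_json(g):
    if g == "inf":
        return math.inf
    return g


def ruleset_to_json(rs: RuleSet) -> dict:
    groups = []
    for g in rs.groups:
        groups.append(
            {
                "group_id": g.group_id,
                "fingerprint": g.fingerprint.to_json(),
                "members": [
                    {"reaction_id": m.reaction_id, "smiles": m.smiles()}
                    for m in g.members
                ],
            }
        )
    rules = []
    for rule in rs.rule_list:
        rules.append(
            {
                "group_id": rule.group_id,
                "diameter": rule.diameter,
                "h_level": rule.h_level,
                "genericity": _genericity_to_json(rule.genericity),
                "simple_rules": [
                    {
                        "smirks": s.smirks,
                        "source_ids": list(s.source_ids),
                        "product_charges": {
                            str(k): v for k, v in s.product_charges.items()
                        },
                    }
                    for s in rule.simple_rules
                ],
            }
        )
    return {
        "target_genericity": _genericity_to_json(rs.target_genericity),
        "max_diameter": rs.max_diameter,
        "functional_groups": [
            {"name": fg.name, "smarts": fg.smarts} for fg in rs.functional_groups
        ],
        "groups": groups,
        "rules": rules,
    }


def ruleset_from_json(data: dict) -> RuleSet:
    groups = []
    for g in data["groups"]:
        members = [
            parse_reaction(m["smiles"], m["reaction_id"]) for m in g["members"]
        ]
        groups.append(
            ReactionGroup(
                group_id=g["group_id"],
                fingerprint=ReactionFingerprint.from_json(g["fingerprint"]),
                members=members,
            )
        )
    rules = {}
    for r in data["rules"]:
        simple = [
            SimpleRule(
                smirks=s["smirks"],
                source_ids=tuple(s["source_ids"]),
                diameter=r["diameter"],
                h_level=r["h_level"],
                product_charges={int(k): v for k, v in s["product_charges"].items()},
            )
            for s in r["simple_rules"]
        ]
        rules[r["group_id"]] = CompositeRule(
            group_id=r["group_id"],
            simple_rules=simple,
            diameter=r["diameter"],
            h_level=r["h_level"],
            genericity=_genericity_from_json(r["genericity"]),
        )
    return RuleSet(
        groups=groups,
        rules=rules,
        target_genericity=_genericity_from_json(data["target_genericity"]),
        functional_groups=[
            FunctionalGroup(fg["name"], fg["smarts"])
            for fg in data.get("functional_groups", [])
        ],
        max_diameter=data.get("max_diameter", 8),
    )


def save_ruleset(path, rs: RuleSet):
    Path(path).write_text(json.dumps(ruleset_to_json(rs), indent=1) + "\n")


def load_ruleset(path) -> RuleSet:
    return ruleset_from_json(json.loads(Path(path).read_text()))
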