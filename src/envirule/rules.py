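"""SMIRKS rule extraction from reaction groups.

One composite rule is generated per eligible reaction group.  The substrate
side of each simple rule is the group's reaction center, expanded breadth
first to an adjustable diameter ``d``; atoms at the expansion frontier are
generalized to element-plus-aromaticity queries, and substituent
environments are attached to center atoms as recursive SMARTS so that the
product side only ever rewrites the center itself.  An explicit-hydrogen
level ``h`` adds total-H-count constraints to atoms within ``h - 1`` bonds
of the center, giving a second, finer specificity knob once the diameter
saturates.

Substrate graphs of different reactions in a group are combined into one
simple rule only when no substituent co-occurrence is created that was not
observed in at least one member reaction; otherwise they stay separate.
This keeps composite rules minimal without over-generalizing.

Genericity of a rule is the ratio NS/PS of compounds the rule fires on
without a matching observed reaction (negative samples) to those with one
(positive samples).  ``tune_genericity`` walks the (diameter, explicit-H)
state path and returns the state whose genericity is closest to a target,
ties broken toward the more generic state.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import (
    CosubstrateConfig,
    DEFAULT_COSUBSTRATES,
    MappedReaction,
    canonical_smiles,
    mol_from_smiles,
)
from .cluster import ReactionGroup
from .fingerprints import FunctionalGroup, ReactionCenter, detect_reaction_center


class RuleConsistencyError(RuntimeError):
    """An emitted rule failed to reproduce one of its source reactions."""


class BackboneMismatchError(RuntimeError):
    """Group members do not share an isomorphic reaction-center backbone."""


# ---------------------------------------------------------------------------
# SMARTS fragment writing
# ---------------------------------------------------------------------------

_BOND_SYMBOL = {
    "1": "-",
    "2": "=",
    "3": "#",
    "ar": ":",
}


def _bond_symbol(bond: Chem.Bond) -> str:
    from .chem import _bond_order_key

    return _BOND_SYMBOL[_bond_order_key(bond)]


def _element_expr(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    return sym.lower() if atom.GetIsAromatic() else sym


def _write_component(mol, atoms, root, atom_expr_fn, order_key):
    """Write one connected induced subgraph as a SMARTS/SMILES fragment.

    Returns ``(fragment_string, atom_output_order)``.  Traversal is a DFS
    with neighbors visited in ``order_key`` order; non-tree edges become
    ring closures.
    """
    atoms = set(atoms)
    visited = set()
    tree_children = defaultdict(list)
    back_edges = []
    order = []

    def explore(i, parent):
        visited.add(i)
        order.append(i)
        nbrs = [
            n.GetIdx()
            for n in mol.GetAtomWithIdx(i).GetNeighbors()
            if n.GetIdx() in atoms
        ]
        for j in sorted(nbrs, key=order_key):
            if j == parent:
                continue
            bond = mol.GetBondBetweenAtoms(i, j)
            if j in visited:
                edge = frozenset((i, j))
                if edge not in {frozenset(e[:2]) for e in back_edges}:
                    back_edges.append((i, j, bond))
            else:
                tree_children[i].append((bond, j))
                explore(j, i)

    explore(root, None)

    closures = defaultdict(list)  # atom -> [(digit, bond_symbol)]
    for digit, (i, j, bond) in enumerate(back_edges, start=1):
        sym = _bond_symbol(bond)
        closures[i].append((digit, sym))
        closures[j].append((digit, sym))

    def render(i):
        s = atom_expr_fn(i)
        for digit, sym in closures[i]:
            s += sym + (str(digit) if digit < 10 else f"%{digit:02d}")
        children = tree_children[i]
        for k, (bond, j) in enumerate(children):
            frag = _bond_symbol(bond) + render(j)
            s += frag if k == len(children) - 1 else f"({frag})"
        return s

    return render(root), order


def _components(mol, atoms):
    atoms = set(atoms)
    seen = set()
    comps = []
    for a in sorted(atoms):
        if a in seen:
            continue
        comp = set()
        queue = deque([a])
        while queue:
            i = queue.popleft()
            if i in comp:
                continue
            comp.add(i)
            for n in mol.GetAtomWithIdx(i).GetNeighbors():
                if n.GetIdx() in atoms and n.GetIdx() not in comp:
                    queue.append(n.GetIdx())
        seen |= comp
        comps.append(comp)
    return comps


def _distances_from(mol, sources):
    """Bond-count distance from a set of atoms, over the whole molecule."""
    dist = {i: 0 for i in sources}
    queue = deque(sources)
    while queue:
        i = queue.popleft()
        for n in mol.GetAtomWithIdx(i).GetNeighbors():
            j = n.GetIdx()
            if j not in dist:
                dist[j] = dist[i] + 1
                queue.append(j)
    return dist


def _core_atom_expr(atom, h_counts=None, env_opts=None, mapnum=None):
    parts = [_element_expr(atom), f"{atom.GetFormalCharge():+d}"]
    if h_counts:
        parts.append(",".join(f"H{n}" for n in sorted(set(h_counts))))
    if env_opts:
        parts.append(",".join(f"$({e})" for e in env_opts))
    body = ";".join(parts)
    if mapnum is not None:
        body += f":{mapnum}"
    return f"[{body}]"


def _env_atom_expr(atom, relaxed, with_h):
    parts = [_element_expr(atom)]
    if not relaxed:
        parts.append(f"{atom.GetFormalCharge():+d}")
    if with_h:
        parts.append(f"H{atom.GetTotalNumHs()}")
    return "[" + ";".join(parts) + "]"


def write_env_smarts(mol, anchor, core_idxs, diameter, h_level, dist, ranks):
    """Recursive-SMARTS environment of one center atom, or None if empty.

    ``dist`` holds bond distances from the center-atom set; atoms at exactly
    ``diameter`` are frontier atoms and are relaxed to element+aromaticity.
    Atoms within ``h_level - 1`` of the center carry total-H constraints.
    """
    if diameter < 1:
        return None
    env = set()
    queue = deque([(anchor, 0)])
    seen = {anchor}
    while queue:
        i, depth = queue.popleft()
        if depth >= diameter:
            continue
        for n in mol.GetAtomWithIdx(i).GetNeighbors():
            j = n.GetIdx()
            if j in core_idxs or j in seen:
                continue
            seen.add(j)
            env.add(j)
            queue.append((j, depth + 1))
    if not env:
        return None

    def expr(i):
        atom = mol.GetAtomWithIdx(i)
        if i == anchor:
            h = [atom.GetTotalNumHs()] if h_level >= 1 else None
            return _core_atom_expr(atom, h_counts=h)
        return _env_atom_expr(
            atom,
            relaxed=dist[i] >= diameter,
            with_h=dist[i] <= h_level - 1,
        )

    frag, _ = _write_component(
        mol, env | {anchor}, anchor, expr, order_key=lambda i: ranks[i]
    )
    return frag


# ---------------------------------------------------------------------------
# rule objects
# ---------------------------------------------------------------------------

_MOL_CACHE: dict = {}


def _cached_mol(smiles: str) -> Chem.Mol:
    mol = _MOL_CACHE.get(smiles)
    if mol is None:
        mol = mol_from_smiles(smiles)
        _MOL_CACHE[smiles] = mol
    return mol


@dataclass
class SimpleRule:
    """One SMIRKS transformation extracted from a (merged) substrate graph."""

    smirks: str
    source_ids: tuple
    diameter: int
    h_level: int
    product_charges: dict = field(default_factory=dict)
    _rxn: object = field(default=None, repr=False, compare=False)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def reaction(self):
        if self._rxn is None:
            rxn = AllChem.ReactionFromSmarts(self.smirks)
            if rxn is None:
                raise RuleConsistencyError(f"unparsable SMIRKS: {self.smirks}")
            rxn.Initialize()
            self._rxn = rxn
        return self._rxn

    def apply(self, compound) -> frozenset:
        """All distinct predicted product sets for one compound.

        Returns a frozenset of frozensets of canonical product SMILES; empty
        when the rule does not trigger (no match, or no chemically valid
        outcome).
        """
        if isinstance(compound, str):
            smiles = compound
            mol = _cached_mol(smiles)
        else:
            mol = compound
            smiles = canonical_smiles(mol)
        cached = self._cache.get(smiles)
        if cached is not None:
            return cached

        outcomes = set()
        try:
            product_sets = self.reaction().RunReactants((mol,))
        except Exception:
            product_sets = ()
        for pset in product_sets:
            smis = []
            ok = True
            for pmol in pset:
                for atom in pmol.GetAtoms():
                    from_template = atom.HasProp("old_mapno") or not atom.HasProp(
                        "react_atom_idx"
                    )
                    if from_template:
                        atom.SetNoImplicit(False)
                        atom.SetNumExplicitHs(0)
                    if atom.HasProp("old_mapno"):
                        mapno = atom.GetIntProp("old_mapno")
                        if mapno in self.product_charges:
                            atom.SetFormalCharge(self.product_charges[mapno])
                    atom.SetAtomMapNum(0)
                try:
                    Chem.SanitizeMol(pmol)
                except Exception:
                    ok = False
                    break
                smis.append(Chem.MolToSmiles(pmol))
            if ok and smis:
                outcomes.add(frozenset(smis))
        result = frozenset(outcomes)
        self._cache[smiles] = result
        return result

    def triggers(self, compound) -> bool:
        return bool(self.apply(compound))


@dataclass
class CompositeRule:
    """All simple rules of one reaction group, sharing one classifier."""

    group_id: str
    simple_rules: list
    diameter: int
    h_level: int
    genericity: Optional[float] = None

    def apply(self, compound) -> frozenset:
        out = set()
        for rule in self.simple_rules:
            out |= rule.apply(compound)
        return frozenset(out)

    def triggers(self, compound) -> bool:
        return any(r.triggers(compound) for r in self.simple_rules)

    def covers(self, reaction: MappedReaction) -> bool:
        observed = reaction.product_smiles
        return observed in self.apply(reaction.substrate_smiles)

    @property
    def smirks_list(self) -> list:
        return [r.smirks for r in self.simple_rules]


# ---------------------------------------------------------------------------
# substrate graphs and combination
# ---------------------------------------------------------------------------


@dataclass
class SubstrateGraph:
    """Per-reaction (or merged) substituent profile over core positions.

    ``profiles`` maps member reaction-id to a tuple of per-position options
    ``(env_smarts_or_None, h_count_or_None)``.
    """

    member_ids: list
    profiles: dict

    def options(self, pos: int) -> list:
        seen = []
        for mid in self.member_ids:
            opt = self.profiles[mid][pos]
            if opt not in seen:
                seen.append(opt)
        return seen


_TRIVIAL = (None, None)


def _merge_legal(profiles: Mapping[str, tuple], member_ids) -> bool:
    """No unobserved substituent co-occurrence across any two positions."""
    if not member_ids:
        return True
    n_pos = len(next(iter(profiles.values())))
    observed = [profiles[m] for m in member_ids]
    for p, q in itertools.combinations(range(n_pos), 2):
        opts_p = {prof[p] for prof in observed}
        opts_q = {prof[q] for prof in observed}
        for op in opts_p:
            for oq in opts_q:
                if op == _TRIVIAL or oq == _TRIVIAL:
                    continue
                if not any(
                    prof[p] == op and prof[q] == oq for prof in observed
                ):
                    return False
    return True


def combine(graphs: Sequence[SubstrateGraph]) -> list:
    """Merge substrate graphs into the fewest legal combined graphs.

    A merge is accepted only if every cross-position substituent pairing in
    the merged graph is observed in at least one member reaction.  Up to
    six input graphs the minimum-size legal partition is found exactly
    (greedy pairwise merging can be suboptimal); beyond that a
    deterministic greedy strategy — largest graph first, then
    lexicographic — is used.
    """
    if 1 < len(graphs) <= 6:
        return _combine_exact(graphs)
    pool = [
        SubstrateGraph(list(g.member_ids), dict(g.profiles)) for g in graphs
    ]
    merged_any = True
    while merged_any:
        merged_any = False
        pool.sort(key=lambda g: (-len(g.member_ids), min(g.member_ids)))
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                candidate = {**pool[i].profiles, **pool[j].profiles}
                members = pool[i].member_ids + pool[j].member_ids
                if _merge_legal(candidate, members):
                    pool[i] = SubstrateGraph(sorted(members), candidate)
                    del pool[j]
                    merged_any = True
                    break
            if merged_any:
                break
    pool.sort(key=lambda g: min(g.member_ids))
    return pool


def _combine_exact(graphs: Sequence[SubstrateGraph]) -> list:
    """Minimum-size legal partition by exhaustive enumeration.

    Deterministic: among minimal partitions, the lexicographically
    smallest (by sorted member-id blocks) wins.
    """
    items = sorted(graphs, key=lambda g: min(g.member_ids))

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [[head] + part[k]] + part[k + 1 :]
            yield part + [[head]]

    best = None
    for part in partitions(items):
        ok = True
        merged = []
        for block in part:
            profiles = {}
            members = []
            for g in block:
                profiles.update(g.profiles)
                members.extend(g.member_ids)
            if not _merge_legal(profiles, members):
                ok = False
                break
            merged.append(SubstrateGraph(sorted(members), profiles))
        if not ok:
            continue
        merged.sort(key=lambda g: min(g.member_ids))
        key = (len(merged), [tuple(g.member_ids) for g in merged])
        if best is None or key < best[0]:
            best = (key, merged)
    assert best is not None  # singletons always form a legal partition
    return best[1]


def optimal_combination_size(graphs: Sequence[SubstrateGraph]) -> int:
    """Brute-force minimum number of legal merged graphs (small groups only)."""
    items = list(graphs)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [[head] + part[k]] + part[k + 1 :]
            yield part + [[head]]

    best = len(items)
    for part in partitions(items):
        if len(part) >= best:
            continue
        ok = True
        for block in part:
            profiles = {}
            members = []
            for g in block:
                profiles.update(g.profiles)
                members.extend(g.member_ids)
            if not _merge_legal(profiles, members):
                ok = False
                break
        if ok:
            best = len(part)
    return best


# ---------------------------------------------------------------------------
# composite-rule construction
# ---------------------------------------------------------------------------


@dataclass
class _MemberContext:
    reaction: MappedReaction
    center: ReactionCenter
    core_atoms: list  # substrate atom indices aligned to template positions
    ranks: list
    dist: dict


def _center_substrate_idxs(reaction: MappedReaction, center: ReactionCenter):
    return [reaction._sub_index[m] for m in sorted(center.atoms)]


def _core_query(reaction: MappedReaction, center: ReactionCenter):
    """Plain core query (no envs/H) used to align members onto the template.

    Returns (query_mol, template_positions) where template_positions[i] is
    the substrate atom index of query atom i in the representative.
    """
    mol = reaction.substrate
    idxs = set(_center_substrate_idxs(reaction, center))
    ranks = list(Chem.CanonicalRankAtoms(Chem.Mol(mol), breakTies=True))
    comps = _components(mol, idxs)
    frags = []
    positions = []
    for comp in sorted(comps, key=lambda c: min(ranks[i] for i in c)):
        root = min(comp, key=lambda i: ranks[i])
        frag, order = _write_component(
            mol,
            comp,
            root,
            lambda i: _core_atom_expr(mol.GetAtomWithIdx(i)),
            order_key=lambda i: ranks[i],
        )
        frags.append(frag)
        positions.extend(order)
    query = Chem.MolFromSmarts(".".join(frags))
    if query is None:
        raise RuleConsistencyError("could not build core query")
    return query, positions


def _align_member(reaction, center, query) -> tuple:
    """Match the representative's core query onto one member's center atoms."""
    mol = reaction.substrate
    want = set(_center_substrate_idxs(reaction, center))
    matches = mol.GetSubstructMatches(query, uniquify=True)
    for match in matches:
        if set(match) == want:
            return match
    raise BackboneMismatchError(
        f"reaction {reaction.reaction_id!r} does not carry the group's "
        "reaction-center backbone (clustering inconsistency)"
    )


def _member_context(reaction, functional_groups) -> _MemberContext:
    center = detect_reaction_center(reaction, functional_groups)
    mol = reaction.substrate
    ranks = list(Chem.CanonicalRankAtoms(Chem.Mol(mol), breakTies=True))
    idxs = _center_substrate_idxs(reaction, center)
    dist = _distances_from(mol, idxs)
    return _MemberContext(reaction, center, idxs, ranks, dist)


def _member_profile(ctx: _MemberContext, match, diameter, h_level):
    """Per-position (env, h) options for one member, aligned to template."""
    mol = ctx.reaction.substrate
    core_set = set(match)
    profile = []
    for anchor in match:
        env = write_env_smarts(
            mol, anchor, core_set, diameter, h_level, ctx.dist, ctx.ranks
        )
        h = mol.GetAtomWithIdx(anchor).GetTotalNumHs() if h_level >= 1 else None
        profile.append((env, h))
    return tuple(profile)


def _emit_simple_rule(
    rep: _MemberContext,
    rep_match,
    graph: SubstrateGraph,
    diameter,
    h_level,
) -> SimpleRule:
    mol = rep.reaction.substrate
    reaction = rep.reaction
    n_pos = len(rep_match)
    mapnum_of_pos = [
        mol.GetAtomWithIdx(rep_match[p]).GetAtomMapNum() for p in range(n_pos)
    ]
    pos_of_idx = {rep_match[p]: p for p in range(n_pos)}

    env_opts = []
    h_opts = []
    for p in range(n_pos):
        opts = graph.options(p)
        envs = [e for e, _ in opts]
        hs = [h for _, h in opts if h is not None]
        env_opts.append(None if any(e is None for e in envs) else sorted(set(envs)))
        # each env option already carries its member's H count on the anchor
        # (h_level >= 1), so a position-level H alternation is emitted only
        # when env constraints are absent; otherwise it would permit
        # unobserved (environment, H-count) cross-combinations
        use_h = h_level >= 1 and hs and env_opts[p] is None
        h_opts.append(sorted(set(hs)) if use_h else None)

    def sub_expr(i):
        p = pos_of_idx[i]
        return _core_atom_expr(
            mol.GetAtomWithIdx(i),
            h_counts=h_opts[p],
            env_opts=env_opts[p],
            mapnum=mapnum_of_pos[p],
        )

    core_set = set(rep_match)
    comps = _components(mol, core_set)
    frags = [
        _write_component(
            mol,
            comp,
            min(comp, key=lambda i: rep.ranks[i]),
            sub_expr,
            order_key=lambda i: rep.ranks[i],
        )[0]
        for comp in sorted(comps, key=lambda c: min(rep.ranks[i] for i in c))
    ]
    lhs = ".".join(frags)
    if len(frags) > 1:
        lhs = f"({lhs})"

    # product side: rewrite the core images plus incoming atoms
    product_charges = {}
    prod_frags = []
    core_maps = set(mapnum_of_pos)
    for pidx, pmol in enumerate(reaction.products):
        atoms = set()
        for atom in pmol.GetAtoms():
            m = atom.GetAtomMapNum()
            if m in core_maps:
                atoms.add(atom.GetIdx())
                product_charges[m] = atom.GetFormalCharge()
            elif (pidx, atom.GetIdx()) in reaction.incoming:
                atoms.add(atom.GetIdx())
        if not atoms:
            if any(a.GetAtomMapNum() > 0 for a in pmol.GetAtoms()):
                raise RuleConsistencyError(
                    f"product {pidx} of reaction {reaction.reaction_id!r} "
                    "contains no reaction-center atom"
                )
            continue
        pranks = list(Chem.CanonicalRankAtoms(Chem.Mol(pmol), breakTies=True))

        def prod_expr(i, _pmol=pmol):
            atom = _pmol.GetAtomWithIdx(i)
            m = atom.GetAtomMapNum()
            body = f"{_element_expr(atom)}{atom.GetFormalCharge():+d}"
            if m in core_maps:
                body += f":{m}"
            return f"[{body}]"

        for comp in sorted(
            _components(pmol, atoms), key=lambda c: min(pranks[i] for i in c)
        ):
            frag, _ = _write_component(
                pmol,
                comp,
                min(comp, key=lambda i: pranks[i]),
                prod_expr,
                order_key=lambda i: pranks[i],
            )
            prod_frags.append(frag)
    rhs = ".".join(prod_frags)

    return SimpleRule(
        smirks=f"{lhs}>>{rhs}",
        source_ids=tuple(graph.member_ids),
        diameter=diameter,
        h_level=h_level,
        product_charges=product_charges,
    )


def aligned_substrate_graphs(
    members: Sequence[MappedReaction],
    diameter: int,
    h_level: int,
    functional_groups: Sequence[FunctionalGroup] = (),
):
    """Single-reaction substrate graphs aligned on one center template.

    Returns ``(representative_context, template_match, graphs)``; every
    graph's positions refer to the same template atom ordering, so
    substituent co-occurrence is comparable across reactions.
    """
    contexts = [_member_context(m, functional_groups) for m in members]
    rep = contexts[0]
    query, positions = _core_query(rep.reaction, rep.center)
    rep_match = tuple(positions)
    graphs = []
    for ctx in contexts:
        match = _align_member(ctx.reaction, ctx.center, query)
        profile = _member_profile(ctx, match, diameter, h_level)
        graphs.append(
            SubstrateGraph(
                member_ids=[ctx.reaction.reaction_id],
                profiles={ctx.reaction.reaction_id: profile},
            )
        )
    return rep, rep_match, graphs


def expand_center(
    reaction: MappedReaction,
    center: ReactionCenter,
    diameter: int,
    h_level: int = 0,
) -> SubstrateGraph:
    """Single-reaction substrate graph: center backbone plus substituents."""
    ctx = _MemberContext(
        reaction,
        center,
        _center_substrate_idxs(reaction, center),
        list(Chem.CanonicalRankAtoms(Chem.Mol(reaction.substrate), breakTies=True)),
        _distances_from(
            reaction.substrate, _center_substrate_idxs(reaction, center)
        ),
    )
    profile = _member_profile(ctx, tuple(ctx.core_atoms), diameter, h_level)
    return SubstrateGraph(
        member_ids=[reaction.reaction_id],
        profiles={reaction.reaction_id: profile},
    )


# simple-rule lists are immutable once built and their application caches
# are expensive to refill, so construction is memoized on the group's
# member reactions and the (diameter, h) state
_RULE_CACHE: dict = {}


def build_composite_rule(
    group: ReactionGroup,
    diameter: int,
    h_level: int,
    functional_groups: Sequence[FunctionalGroup] = (),
    check_coverage: bool = True,
) -> CompositeRule:
    """Extract the composite rule of one group at a fixed (diameter, h) state."""
    cache_key = (
        tuple(sorted(m.smiles() for m in group.members)),
        diameter,
        h_level,
        tuple((fg.name, fg.smarts) for fg in functional_groups),
    )
    cached = _RULE_CACHE.get(cache_key)
    if cached is not None:
        return CompositeRule(
            group_id=group.group_id,
            simple_rules=cached,
            diameter=diameter,
            h_level=h_level,
        )
    rep, rep_match, graphs = aligned_substrate_graphs(
        group.members, diameter, h_level, functional_groups
    )
    merged = combine(graphs)
    simple_rules = [
        _emit_simple_rule(rep, rep_match, g, diameter, h_level) for g in merged
    ]
    rule = CompositeRule(
        group_id=group.group_id,
        simple_rules=simple_rules,
        diameter=diameter,
        h_level=h_level,
    )
    if check_coverage:
        for member in group.members:
            if not rule.covers(member):
                raise RuleConsistencyError(
                    f"rule for {group.group_id} at d={diameter}, h={h_level} "
                    f"fails to reproduce reaction {member.reaction_id!r}"
                )
        _RULE_CACHE[cache_key] = simple_rules
    return rule


def saturation_diameter(
    group: ReactionGroup,
    functional_groups: Sequence[FunctionalGroup] = (),
    max_diameter: int = 8,
) -> int:
    """Smallest diameter at which expansion covers every member substrate."""
    worst = 0
    for member in group.members:
        ctx = _member_context(member, functional_groups)
        if ctx.dist:
            worst = max(worst, max(ctx.dist.values()))
    return min(worst, max_diameter)


# ---------------------------------------------------------------------------
# genericity
# ---------------------------------------------------------------------------


def build_observed_index(reactions: Sequence[MappedReaction]) -> dict:
    """substrate canonical SMILES -> set of observed product SMILES-sets."""
    index: dict = defaultdict(set)
    for r in reactions:
        index[r.substrate_smiles].add(r.product_smiles)
    return dict(index)


def compute_genericity(
    rule: CompositeRule,
    compounds: Sequence[str],
    observed: Mapping[str, set],
):
    """NS/PS of a rule over a compound set.

    Returns ``math.inf`` when the rule fires only on compounds without an
    observed matching reaction, and ``None`` when it never fires.
    """
    ps = ns = 0
    for compound in compounds:
        smiles = canonical_smiles(compound)
        outcomes = rule.apply(smiles)
        if not outcomes:
            continue
        if any(o in observed.get(smiles, ()) for o in outcomes):
            ps += 1
        else:
            ns += 1
    if ps == 0 and ns == 0:
        return None
    if ps == 0:
        return math.inf
    return ns / ps


def _state_path(d_sat: int) -> list:
    states = [(d, 0) for d in range(d_sat + 1)]
    states += [(d_sat, h) for h in range(1, d_sat + 2)]
    return states


def tune_genericity(
    group: ReactionGroup,
    target: float,
    compounds: Sequence[str],
    observed: Mapping[str, set],
    functional_groups: Sequence[FunctionalGroup] = (),
    max_diameter: int = 8,
) -> CompositeRule:
    """Choose the (diameter, explicit-H) state with genericity closest to target.

    The state path runs from most generic (d=0, h=0) through increasing
    diameters to saturation, then increasing explicit-H levels.  An infinite
    genericity counts as more generic than any target; ties are broken
    toward the more generic (earlier) state.  The returned rule always
    covers every group reaction.
    """
    d_sat = saturation_diameter(group, functional_groups, max_diameter)
    best = None
    for d, h in _state_path(d_sat):
        rule = build_composite_rule(group, d, h, functional_groups)
        g = compute_genericity(rule, compounds, observed)
        rule.genericity = g
        if g is None:
            distance = math.inf
        elif math.isinf(g):
            distance = math.inf if not math.isinf(target) else 0.0
        else:
            distance = abs(g - target)
        if best is None or distance < best[0]:
            best = (distance, rule)
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# rule sets
# ---------------------------------------------------------------------------


@dataclass
class RuleSet:
    """Persisted groups, fingerprints and composite rules.

    The object the reaction adder updates: singleton groups keep their
    stored fingerprints so that later reactions can make them eligible.
    """

    groups: list
    rules: dict  # group_id -> CompositeRule
    target_genericity: float
    functional_groups: list = field(default_factory=list)
    max_diameter: int = 8

    @property
    def rule_list(self) -> list:
        return [self.rules[g.group_id] for g in self.groups if g.group_id in self.rules]

    @property
    def rule_ids(self) -> list:
        return [r.group_id for r in self.rule_list]

    def group_by_id(self, group_id: str) -> ReactionGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def apply_all(self, compound) -> dict:
        """group_id -> outcomes for every rule that triggers on the compound."""
        out = {}
        for rule in self.rule_list:
            outcomes = rule.apply(compound)
            if outcomes:
                out[rule.group_id] = outcomes
        return out


def generate_ruleset(
    groups: Sequence[ReactionGroup],
    target_genericity: float,
    compounds: Sequence[str],
    observed: Mapping[str, set],
    functional_groups: Sequence[FunctionalGroup] = (),
    max_diameter: int = 8,
    tune: bool = True,
) -> RuleSet:
    """One tuned composite rule per eligible group; fingerprints persisted."""
    rules = {}
    for group in groups:
        if not group.eligible:
            continue
        if tune:
            rule = tune_genericity(
                group,
                target_genericity,
                compounds,
                observed,
                functional_groups,
                max_diameter,
            )
        else:
            rule = build_composite_rule(group, 0, 0, functional_groups)
            rule.genericity = compute_genericity(rule, compounds, observed)
        rules[group.group_id] = rule
    return RuleSet(
        groups=list(groups),
        rules=rules,
        target_genericity=target_genericity,
        functional_groups=list(functional_groups),
        max_diameter=max_diameter,
    )
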