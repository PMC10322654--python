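"""Reaction centers and multi-part reaction fingerprints.

The reaction center of a mapped reaction contains every changed bond
(formed, cleaved, or order-changed), the endpoints of those bonds, atoms
whose hydrogen count or formal charge changed, and — when any of those atoms
intersects a match of a configured functional-group SMARTS — the whole
functional group.

Fingerprints are exact multisets of canonical descriptor strings in three
parts (bond formation/cleavage, bond order change, reaction-center atoms).
Two reactions belong to the same group iff their fingerprints have Tanimoto
similarity exactly 1.0, which with multiset descriptors is plain equality —
no hashing, no collisions.

Center-atom descriptors are deliberately restricted to the center subgraph:
an atom is described by its element/aromaticity/charge, its bonds to other
center atoms before and after the reaction, and its hydrogen/charge deltas.
Neighbors outside the center do not contribute, so e.g. oxidation of a
primary and of a secondary alcohol — same changed C-O bond, same C-H loss —
share one fingerprint and one group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem

from .chem import MappedReaction, _bond_order_key


@dataclass(frozen=True)
class FunctionalGroup:
    name: str
    smarts: str

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ValueError(f"invalid functional-group SMARTS {self.smarts!r}")
        return q


@dataclass
class ReactionCenter:
    """Changed atoms/bonds of one reaction, plus completed functional groups.

    Atoms are identified by substrate map numbers; incoming (cosubstrate)
    atoms, having no map, are identified by ``(product_idx, atom_idx)``.
    """

    atoms: frozenset  # substrate map numbers
    incoming_atoms: frozenset  # (pidx, aidx)
    cleaved_bonds: tuple  # ((mapnum, mapnum) sorted, order)
    formed_bonds: tuple  # ((key, key) sorted, order); key=mapnum or ("in",pidx,aidx)
    order_changed_bonds: tuple  # ((mapnum, mapnum), order_before, order_after)
    completed_groups: tuple = ()  # (name, sorted mapnums)

    @property
    def is_empty(self) -> bool:
        return (
            not self.cleaved_bonds
            and not self.formed_bonds
            and not self.order_changed_bonds
            and not self.atoms
            and not self.incoming_atoms
        )


def _atom_tag(atom: Chem.Atom) -> str:
    arom = "a" if atom.GetIsAromatic() else ""
    ring = "R" if atom.IsInRing() else ""
    chg = atom.GetFormalCharge()
    chg_s = f"{chg:+d}" if chg else ""
    return f"{atom.GetSymbol()}{arom}{ring}{chg_s}"


def detect_reaction_center(
    reaction: MappedReaction,
    functional_groups: Sequence[FunctionalGroup] = (),
) -> ReactionCenter:
    sub = reaction.substrate
    changed_atoms = set()
    cleaved = []
    formed = []
    order_changed = []

    # substrate bonds: cleaved or order-changed
    for bond in sub.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        ma, mb = a.GetAtomMapNum(), b.GetAtomMapNum()
        pair = tuple(sorted((ma, mb)))
        if ma in reaction.leaving or mb in reaction.leaving:
            cleaved.append((pair, _bond_order_key(bond)))
            changed_atoms.update(pair)
            continue
        pa, pb = reaction.mapping[ma], reaction.mapping[mb]
        if pa[0] != pb[0]:
            cleaved.append((pair, _bond_order_key(bond)))
            changed_atoms.update(pair)
            continue
        pbond = reaction.products[pa[0]].GetBondBetweenAtoms(pa[1], pb[1])
        if pbond is None:
            cleaved.append((pair, _bond_order_key(bond)))
            changed_atoms.update(pair)
        elif _bond_order_key(pbond) != _bond_order_key(bond):
            order_changed.append((pair, _bond_order_key(bond), _bond_order_key(pbond)))
            changed_atoms.update(pair)

    # product bonds: formed (between mapped atoms, or involving incoming atoms)
    incoming_atoms = set(reaction.incoming)
    inv = {v: k for k, v in reaction.mapping.items()}
    for pidx, pmol in enumerate(reaction.products):
        for bond in pmol.GetBonds():
            u = (pidx, bond.GetBeginAtomIdx())
            v = (pidx, bond.GetEndAtomIdx())
            ku = inv.get(u, ("in",) + u)
            kv = inv.get(v, ("in",) + v)
            has_incoming = u in incoming_atoms or v in incoming_atoms
            if not has_incoming:
                sbond = sub.GetBondBetweenAtoms(
                    reaction._sub_index[ku], reaction._sub_index[kv]
                )
                if sbond is not None:
                    continue
            pair = tuple(sorted((ku, kv), key=str))
            formed.append((pair, _bond_order_key(bond)))
            for k in (ku, kv):
                if isinstance(k, int):
                    changed_atoms.add(k)

    # hydrogen-count or charge changes
    for num in reaction.map_numbers:
        if num in reaction.leaving:
            continue
        sa = reaction.substrate_atom(num)
        pa = reaction.product_atom(num)
        if sa.GetTotalNumHs() != pa.GetTotalNumHs() or (
            sa.GetFormalCharge() != pa.GetFormalCharge()
        ):
            changed_atoms.add(num)

    # complete functional groups intersecting the changed atoms
    completed = []
    if functional_groups and changed_atoms:
        idx_to_map = {
            a.GetIdx(): a.GetAtomMapNum() for a in sub.GetAtoms()
        }
        for fg in functional_groups:
            for match in sub.GetSubstructMatches(fg.query(), uniquify=True):
                maps = tuple(sorted(idx_to_map[i] for i in match))
                if set(maps) & changed_atoms:
                    completed.append((fg.name, maps))
                    changed_atoms.update(maps)
    completed.sort()

    return ReactionCenter(
        atoms=frozenset(changed_atoms),
        incoming_atoms=frozenset(incoming_atoms),
        cleaved_bonds=tuple(sorted(cleaved)),
        formed_bonds=tuple(sorted(formed, key=str)),
        order_changed_bonds=tuple(sorted(order_changed)),
        completed_groups=tuple(completed),
    )


@dataclass
class ReactionFingerprint:
    """Three part-tagged descriptor multisets summarizing a reaction center."""

    formation_cleavage: Counter = field(default_factory=Counter)
    bond_change: Counter = field(default_factory=Counter)
    center: Counter = field(default_factory=Counter)

    def tagged(self) -> Counter:
        out: Counter = Counter()
        for tag, part in (
            ("fc", self.formation_cleavage),
            ("bc", self.bond_change),
            ("ct", self.center),
        ):
            for desc, n in part.items():
                out[(tag, desc)] += n
        return out

    def key(self) -> tuple:
        """Hashable canonical form; equal keys iff Tanimoto 1.0."""
        return tuple(sorted(self.tagged().items()))

    @property
    def is_empty(self) -> bool:
        return not (self.formation_cleavage or self.bond_change or self.center)

    def to_json(self) -> dict:
        return {
            "formation_cleavage": sorted(self.formation_cleavage.elements()),
            "bond_change": sorted(self.bond_change.elements()),
            "center": sorted(self.center.elements()),
        }

    @classmethod
    def from_json(cls, data: dict) -> "ReactionFingerprint":
        return cls(
            formation_cleavage=Counter(data["formation_cleavage"]),
            bond_change=Counter(data["bond_change"]),
            center=Counter(data["center"]),
        )


def _endpoint_desc(reaction: MappedReaction, key) -> str:
    if isinstance(key, int):
        return _atom_tag(reaction.substrate_atom(key))
    _, pidx, aidx = key
    return "in:" + _atom_tag(reaction.products[pidx].GetAtomWithIdx(aidx))


def _center_bonds(reaction, mapnum, center_maps, side):
    """Sorted (order, neighbor tag) bonds from one center atom to others."""
    out = []
    if side == "before":
        atom = reaction.substrate_atom(mapnum)
        mol = reaction.substrate
        for nbr in atom.GetNeighbors():
            n = nbr.GetAtomMapNum()
            if n in center_maps:
                bond = mol.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
                out.append(f"{_bond_order_key(bond)}{_atom_tag(nbr)}")
    else:
        if mapnum in reaction.leaving:
            return ["-"]
        pidx, aidx = reaction.mapping[mapnum]
        mol = reaction.products[pidx]
        atom = mol.GetAtomWithIdx(aidx)
        inv = {v: k for k, v in reaction.mapping.items()}
        for nbr in atom.GetNeighbors():
            key = (pidx, nbr.GetIdx())
            n = inv.get(key)
            if n in center_maps or key in reaction.incoming:
                bond = mol.GetBondBetweenAtoms(aidx, nbr.GetIdx())
                out.append(f"{_bond_order_key(bond)}{_atom_tag(nbr)}")
    return sorted(out)


def fingerprint(
    reaction: MappedReaction, center: ReactionCenter
) -> ReactionFingerprint:
    fp = ReactionFingerprint()
    for pair, order in center.cleaved_bonds:
        ends = sorted(_endpoint_desc(reaction, k) for k in pair)
        fp.formation_cleavage[f"cleaved|{ends[0]}~{ends[1]}|{order}"] += 1
    for pair, order in center.formed_bonds:
        ends = sorted(_endpoint_desc(reaction, k) for k in pair)
        fp.formation_cleavage[f"formed|{ends[0]}~{ends[1]}|{order}"] += 1
    for pair, before, after in center.order_changed_bonds:
        ends = sorted(_endpoint_desc(reaction, k) for k in pair)
        fp.bond_change[f"{ends[0]}~{ends[1]}|{before}>{after}"] += 1

    center_maps = set(center.atoms)
    for num in sorted(center_maps):
        sa = reaction.substrate_atom(num)
        before = ",".join(_center_bonds(reaction, num, center_maps, "before"))
        after = ",".join(_center_bonds(reaction, num, center_maps, "after"))
        if num in reaction.leaving:
            dh, dq = "-", "-"
        else:
            pa = reaction.product_atom(num)
            dh = pa.GetTotalNumHs() - sa.GetTotalNumHs()
            dq = pa.GetFormalCharge() - sa.GetFormalCharge()
        fp.center[f"{_atom_tag(sa)}|[{before}]>[{after}]|dH{dh}|dq{dq}"] += 1
    for pidx, aidx in sorted(center.incoming_atoms):
        atom = reaction.products[pidx].GetAtomWithIdx(aidx)
        fp.center[f"in:{_atom_tag(atom)}"] += 1
    return fp


def fingerprint_reaction(
    reaction: MappedReaction,
    functional_groups: Sequence[FunctionalGroup] = (),
) -> ReactionFingerprint:
    return fingerprint(reaction, detect_reaction_center(reaction, functional_groups))


def tanimoto(a: ReactionFingerprint, b: ReactionFingerprint) -> float:
    """Multiset Tanimoto over the part-tagged union of all three parts.

    Two empty fingerprints (identity reactions) are identical by convention.
    """
    ta, tb = a.tagged(), b.tagged()
    inter = sum((ta & tb).values())
    union = sum((ta | tb).values())
    if union == 0:
        return 1.0
    return inter / union
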