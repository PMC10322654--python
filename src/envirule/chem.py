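"""Molecules, mapped reactions and atom-atom mapping.

Every downstream stage (clustering, rule generation, evaluation) consumes
:class:`MappedReaction` objects: a single substrate molecule, one or more
product molecules, and a bijection between their heavy atoms expressed as
SMILES atom-map numbers.  Reactions may arrive pre-mapped (the first-class
input path) or be mapped internally by :func:`map_atoms`, a minimal-bond-edit
mapper intended for small molecules.

Biotransformation datasets record single-substrate decomposition reactions
and routinely omit small cosubstrates (water, O2) and leaving groups
(halide ions, oxygens reduced away).  A :class:`CosubstrateConfig` therefore
exempts a configurable set of elements from the bijection: product atoms with
no substrate counterpart are tagged *incoming*, substrate atoms with no
product counterpart are tagged *leaving*.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class ReactionParseError(ValueError):
    """Raised for syntactically invalid reaction SMILES."""


class ReactionShapeError(ValueError):
    """Raised when a reaction is not single-substrate decomposition shaped."""


class MappingError(ValueError):
    """Raised for invalid or impossible atom-atom mappings."""


class MappingBudgetError(MappingError):
    """Raised when the mapping search space exceeds the configured budget."""


@dataclass(frozen=True)
class CosubstrateConfig:
    """Elements exempt from the substrate/product atom bijection.

    ``incoming`` lists elements that may appear in products without a
    substrate counterpart (water- or O2-derived atoms); ``leaving`` lists
    elements that may disappear from the substrate (halides, reduced
    oxygens).  Both default to the common biotransformation cosubstrates.
    """

    incoming: frozenset = frozenset({"O"})
    leaving: frozenset = frozenset({"O", "F", "Cl", "Br", "I"})


DEFAULT_COSUBSTRATES = CosubstrateConfig()


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ReactionParseError(f"invalid SMILES: {smiles!r}")
    return mol


def canonical_smiles(mol_or_smiles) -> str:
    """Canonical SMILES with atom maps stripped.

    One canonicalization dialect is used everywhere: compound identity in
    pathway graphs and observed-reaction lookups is string equality on this
    form.
    """
    if isinstance(mol_or_smiles, str):
        mol = mol_from_smiles(mol_or_smiles)
    else:
        mol = Chem.Mol(mol_or_smiles)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def strip_maps(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


@dataclass
class UnmappedReaction:
    """A parsed reaction without atom maps, awaiting :func:`map_atoms`."""

    substrate: Chem.Mol
    products: list
    reaction_id: str = ""

    @property
    def substrate_smiles(self) -> str:
        return canonical_smiles(self.substrate)

    @property
    def product_smiles(self) -> frozenset:
        return frozenset(canonical_smiles(p) for p in self.products)


@dataclass
class MappedReaction:
    """A single-substrate reaction with a heavy-atom bijection.

    ``mapping`` sends each substrate map number to ``(product_index,
    atom_index)``.  ``leaving`` holds substrate map numbers with no product
    image; ``incoming`` holds ``(product_index, atom_index)`` pairs with no
    substrate preimage.
    """

    substrate: Chem.Mol
    products: list
    mapping: dict
    reaction_id: str = ""
    leaving: frozenset = frozenset()
    incoming: frozenset = frozenset()

    def __post_init__(self):
        self._sub_index = {
            a.GetAtomMapNum(): a.GetIdx()
            for a in self.substrate.GetAtoms()
            if a.GetAtomMapNum() > 0
        }

    # -- accessors ---------------------------------------------------------
    def substrate_atom(self, mapnum: int) -> Chem.Atom:
        return self.substrate.GetAtomWithIdx(self._sub_index[mapnum])

    def product_atom(self, mapnum: int) -> Chem.Atom:
        pidx, aidx = self.mapping[mapnum]
        return self.products[pidx].GetAtomWithIdx(aidx)

    @property
    def map_numbers(self) -> list:
        return sorted(self._sub_index)

    @property
    def substrate_smiles(self) -> str:
        return canonical_smiles(self.substrate)

    @property
    def product_smiles(self) -> frozenset:
        return frozenset(canonical_smiles(p) for p in self.products)

    def smiles(self) -> str:
        """Mapped reaction SMILES (round-trips through :func:`parse_reaction`)."""
        lhs = Chem.MolToSmiles(self.substrate)
        rhs = ".".join(Chem.MolToSmiles(p) for p in self.products)
        return f"{lhs}>>{rhs}"


def _validate_mapping(
    substrate: Chem.Mol,
    products: Sequence[Chem.Mol],
    cosub: CosubstrateConfig,
    reaction_id: str,
) -> MappedReaction:
    sub_maps: dict = {}
    for atom in substrate.GetAtoms():
        num = atom.GetAtomMapNum()
        if num <= 0:
            raise MappingError(
                f"reaction {reaction_id!r}: substrate atom without map number "
                "in a mapped reaction"
            )
        if num in sub_maps:
            raise MappingError(
                f"reaction {reaction_id!r}: duplicate substrate map {num}"
            )
        sub_maps[num] = atom

    mapping: dict = {}
    incoming = set()
    for pidx, pmol in enumerate(products):
        for atom in pmol.GetAtoms():
            num = atom.GetAtomMapNum()
            if num <= 0:
                if atom.GetSymbol() not in cosub.incoming:
                    raise MappingError(
                        f"reaction {reaction_id!r}: unmapped product atom "
                        f"{atom.GetSymbol()} is not an allowed incoming element"
                    )
                incoming.add((pidx, atom.GetIdx()))
                continue
            if num in mapping:
                raise MappingError(
                    f"reaction {reaction_id!r}: duplicate product map {num}"
                )
            if num not in sub_maps:
                raise MappingError(
                    f"reaction {reaction_id!r}: product map {num} has no "
                    "substrate counterpart"
                )
            if atom.GetSymbol() != sub_maps[num].GetSymbol():
                raise MappingError(
                    f"reaction {reaction_id!r}: map {num} pairs "
                    f"{sub_maps[num].GetSymbol()} with {atom.GetSymbol()}"
                )
            mapping[num] = (pidx, atom.GetIdx())

    leaving = set()
    for num, atom in sub_maps.items():
        if num not in mapping:
            if atom.GetSymbol() not in cosub.leaving:
                raise MappingError(
                    f"reaction {reaction_id!r}: substrate atom {atom.GetSymbol()} "
                    f"(map {num}) has no product image and is not an allowed "
                    "leaving element"
                )
            leaving.add(num)

    return MappedReaction(
        substrate=substrate,
        products=list(products),
        mapping=mapping,
        reaction_id=reaction_id,
        leaving=frozenset(leaving),
        incoming=frozenset(incoming),
    )


def parse_reaction(
    line: str,
    reaction_id: str = "",
    cosub: CosubstrateConfig = DEFAULT_COSUBSTRATES,
):
    """Parse one reaction SMILES ``substrate>>product1.product2``.

    Returns a :class:`MappedReaction` when atom maps are present and form a
    valid bijection (modulo cosubstrate exemptions), else an
    :class:`UnmappedReaction`.
    """
    parts = line.strip().split(">>")
    if len(parts) != 2:
        raise ReactionParseError(
            f"reaction {reaction_id!r}: expected exactly one '>>' in {line!r}"
        )
    lhs, rhs = parts
    substrate = mol_from_smiles(lhs)
    if len(Chem.GetMolFrags(substrate)) != 1:
        raise ReactionShapeError(
            f"reaction {reaction_id!r}: substrate side has more than one "
            "connected component (single-substrate decomposition expected)"
        )
    product_side = mol_from_smiles(rhs)
    products = list(Chem.GetMolFrags(product_side, asMols=True))
    if not products:
        raise ReactionShapeError(f"reaction {reaction_id!r}: no products")

    any_map = any(a.GetAtomMapNum() > 0 for a in substrate.GetAtoms()) or any(
        a.GetAtomMapNum() > 0 for p in products for a in p.GetAtoms()
    )
    if not any_map:
        return UnmappedReaction(substrate, products, reaction_id)
    return _validate_mapping(substrate, products, cosub, reaction_id)


# ---------------------------------------------------------------------------
# internal minimal-bond-edit atom-atom mapper
# ---------------------------------------------------------------------------


def _bond_order_key(bond: Chem.Bond) -> str:
    if bond.GetIsAromatic():
        return "ar"
    return {
        Chem.BondType.SINGLE: "1",
        Chem.BondType.DOUBLE: "2",
        Chem.BondType.TRIPLE: "3",
        Chem.BondType.AROMATIC: "ar",
    }.get(bond.GetBondType(), str(bond.GetBondType()))


def count_changed_bonds(
    substrate: Chem.Mol,
    products: Sequence[Chem.Mol],
    assignment: Mapping[int, tuple],
    leaving: Iterable[int] = (),
    incoming: Iterable[tuple] = (),
) -> int:
    """Number of formed + cleaved + order-changed heavy-atom bonds.

    ``assignment`` maps substrate atom indices to ``(product_idx, atom_idx)``.
    """
    leaving = set(leaving)
    incoming = set(incoming)
    changed = 0
    # substrate-side bonds: cleaved or order-changed
    for bond in substrate.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in leaving or j in leaving:
            changed += 1
            continue
        pi, ai = assignment[i]
        pj, aj = assignment[j]
        if pi != pj:
            changed += 1
            continue
        pbond = products[pi].GetBondBetweenAtoms(ai, aj)
        if pbond is None:
            changed += 1
        elif _bond_order_key(pbond) != _bond_order_key(bond):
            changed += 1
    # product-side bonds absent from the substrate: formed
    back = {v: k for k, v in assignment.items()}
    for pidx, pmol in enumerate(products):
        for bond in pmol.GetBonds():
            u = (pidx, bond.GetBeginAtomIdx())
            v = (pidx, bond.GetEndAtomIdx())
            if u in incoming or v in incoming:
                changed += 1
                continue
            su, sv = back.get(u), back.get(v)
            if su is None or sv is None:
                continue
            if substrate.GetBondBetweenAtoms(su, sv) is None:
                changed += 1
    return changed


def _canonical_order(mol: Chem.Mol) -> list:
    ranks = list(Chem.CanonicalRankAtoms(Chem.Mol(mol), breakTies=True))
    return sorted(range(mol.GetNumAtoms()), key=lambda i: ranks[i])


def map_atoms(
    reaction: UnmappedReaction,
    cosub: CosubstrateConfig = DEFAULT_COSUBSTRATES,
    max_assignments: int = 2_000_000,
) -> MappedReaction:
    """Assign a heavy-atom bijection minimizing the number of changed bonds.

    Exhaustive over element-respecting bijections, so intended for small
    molecules (the pre-mapped input path is first class for anything larger).
    Deterministic: atoms are enumerated in canonical rank order, so ties are
    broken identically for any input atom ordering.
    """
    substrate = reaction.substrate
    products = reaction.products

    sub_by_elem: dict = {}
    for idx in _canonical_order(substrate):
        atom = substrate.GetAtomWithIdx(idx)
        sub_by_elem.setdefault(atom.GetSymbol(), []).append(idx)
    prod_by_elem: dict = {}
    for pidx, pmol in enumerate(products):
        for aidx in _canonical_order(pmol):
            atom = pmol.GetAtomWithIdx(aidx)
            prod_by_elem.setdefault(atom.GetSymbol(), []).append((pidx, aidx))

    elements = sorted(set(sub_by_elem) | set(prod_by_elem))
    total = 1.0
    for elem in elements:
        ns = len(sub_by_elem.get(elem, []))
        np_ = len(prod_by_elem.get(elem, []))
        if ns > np_:
            if elem not in cosub.leaving:
                raise MappingError(
                    f"reaction {reaction.reaction_id!r}: substrate has "
                    f"{ns - np_} extra {elem} atom(s) and {elem} is not an "
                    "allowed leaving element"
                )
            total *= math.comb(ns, np_) * math.factorial(np_)
        elif np_ > ns:
            if elem not in cosub.incoming:
                raise MappingError(
                    f"reaction {reaction.reaction_id!r}: products have "
                    f"{np_ - ns} extra {elem} atom(s) and {elem} is not an "
                    "allowed incoming element"
                )
            total *= math.comb(np_, ns) * math.factorial(ns)
        else:
            total *= math.factorial(ns)
    if total > max_assignments:
        raise MappingBudgetError(
            f"reaction {reaction.reaction_id!r}: ~{total:.0f} candidate "
            f"mappings exceed the budget of {max_assignments}; provide a "
            "pre-mapped reaction SMILES instead"
        )

    def element_assignments(elem):
        subs = sub_by_elem.get(elem, [])
        prods = prod_by_elem.get(elem, [])
        if len(subs) <= len(prods):
            # choose images for every substrate atom; surplus products incoming
            for images in itertools.permutations(prods, len(subs)):
                used = set(images)
                inc = [p for p in prods if p not in used]
                yield dict(zip(subs, images)), [], inc
        else:
            for stay in itertools.combinations(subs, len(prods)):
                leave = [s for s in subs if s not in stay]
                for images in itertools.permutations(prods):
                    yield dict(zip(stay, images)), leave, []

    best = None
    for combo in itertools.product(*(element_assignments(e) for e in elements)):
        assignment: dict = {}
        leaving: list = []
        incoming: list = []
        for amap, leave, inc in combo:
            assignment.update(amap)
            leaving.extend(leave)
            incoming.extend(inc)
        cost = count_changed_bonds(substrate, products, assignment, leaving, incoming)
        if best is None or cost < best[0]:
            best = (cost, assignment, leaving, incoming)

    assert best is not None
    _, assignment, leaving, incoming = best

    # write map numbers onto copies, numbered by substrate canonical order
    sub = Chem.Mol(substrate)
    prods = [Chem.Mol(p) for p in products]
    next_map = 1
    mapping: dict = {}
    leaving_maps = set()
    for idx in _canonical_order(substrate):
        sub.GetAtomWithIdx(idx).SetAtomMapNum(next_map)
        if idx in leaving:
            leaving_maps.add(next_map)
        else:
            pidx, aidx = assignment[idx]
            prods[pidx].GetAtomWithIdx(aidx).SetAtomMapNum(next_map)
            mapping[next_map] = (pidx, aidx)
        next_map += 1
    return MappedReaction(
        substrate=sub,
        products=prods,
        mapping=mapping,
        reaction_id=reaction.reaction_id,
        leaving=frozenset(leaving_maps),
        incoming=frozenset(incoming),
    )


def ensure_mapped(
    reaction,
    cosub: CosubstrateConfig = DEFAULT_COSUBSTRATES,
) -> MappedReaction:
    if isinstance(reaction, MappedReaction):
        return reaction
    return map_atoms(reaction, cosub=cosub)
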