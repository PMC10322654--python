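"""Deterministic synthetic reaction families and pathways.

Real biotransformation corpora are families of reactions that share a
reaction center but differ in substituents, often with several products,
chained into multi-generation pathways.  This module generates such data
programmatically so every code path can be exercised with no external
database: reaction families (dechlorination, alcohol oxidation, ester
hydrolysis, nitro reduction) built from substituent pools, noise compounds
that trigger rules without observed reactions, and rooted pathway graphs.

All randomness flows from an explicit seed; generation is reproducible
byte for byte.  Templates and transforms are validated at generation time
(substrates must parse, carry exactly one reaction site, and yield
sanitizable products), so a bad pool entry fails loudly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from .chem import MappedReaction, canonical_smiles, mol_from_smiles, parse_reaction
from .pathways import PathwayGraph


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reaction families
# ---------------------------------------------------------------------------


def _mapped(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    ranks = list(Chem.CanonicalRankAtoms(out, breakTies=True))
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(ranks[atom.GetIdx()] + 1)
    return out


def _transform_dechlorination(mol, match):
    rw = Chem.RWMol(mol)
    _, cl = match
    rw.RemoveAtom(cl)
    return rw


def _transform_oxidation(mol, match):
    rw = Chem.RWMol(mol)
    c, o = match
    rw.GetBondBetweenAtoms(c, o).SetBondType(Chem.BondType.DOUBLE)
    return rw


def _transform_ester_hydrolysis(mol, match):
    rw = Chem.RWMol(mol)
    _, _, oester, calkyl = match
    rw.RemoveBond(oester, calkyl)
    new_o = rw.AddAtom(Chem.Atom(8))  # water-derived oxygen, unmapped
    rw.AddBond(calkyl, new_o, Chem.BondType.SINGLE)
    return rw


def _transform_nitro_reduction(mol, match):
    rw = Chem.RWMol(mol)
    n, o1, o2 = match
    for idx in sorted((o1, o2), reverse=True):
        rw.RemoveAtom(idx)
    atom = rw.GetAtomWithIdx(n)
    atom.SetFormalCharge(0)
    atom.SetNumExplicitHs(0)
    atom.SetNoImplicit(False)
    return rw


@dataclass(frozen=True)
class ReactionFamily:
    """A center template with a deterministic product-building transform."""

    name: str
    template: str  # format string; substituent slots {0}, {1}, ...
    center_smarts: str
    transform: Callable
    n_slots: int


FAMILIES = {
    f.name: f
    for f in [
        ReactionFamily(
            "dechlorination",
            "Cl{0}",
            "[CX4][Cl]",
            _transform_dechlorination,
            1,
        ),
        ReactionFamily(
            "alcohol_oxidation",
            "{0}C(O){1}",
            "[CX4;H1,H2][OX2H]",
            _transform_oxidation,
            2,
        ),
        ReactionFamily(
            "alcohol_oxidation_primary",
            "{0}CO",
            "[CX4;H1,H2][OX2H]",
            _transform_oxidation,
            1,
        ),
        ReactionFamily(
            "ester_hydrolysis",
            "{0}C(=O)O{1}",
            "[CX3](=[OX1])[OX2H0][#6]",
            _transform_ester_hydrolysis,
            2,
        ),
        ReactionFamily(
            "nitro_reduction",
            "{0}[N+](=O)[O-]",
            "[NX3+](=[OX1])[OX1-]",
            _transform_nitro_reduction,
            1,
        ),
    ]
}

# substituent pools kept free of other families' trigger groups, so rules
# of different families never fire on each other's substrates
DEFAULT_POOLS = {
    "dechlorination": [
        ["CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CCC(C)C", "CCCCCC",
         "CC(C)CC", "CCCCCCC", "CC(CC)CC", "CCCCCCCC", "CCC(C)CC",
         "CCCCCCCCC", "CC(C)CCC", "CCCCC(C)C"],
    ],
    "alcohol_oxidation": [
        ["CC", "CCC", "CCCC", "CC(C)C", "CCCCC"],
        ["C", "CC", "CCC", "C(C)C", "CCCC"],
    ],
    "alcohol_oxidation_primary": [
        ["CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CCC(C)C", "CCCCCC",
         "CC(C)CC", "CCCCCCC", "CCCCCCCC"],
    ],
    "ester_hydrolysis": [
        ["C", "CC", "CCC", "C(C)C", "CCCC"],
        ["C", "CC", "CCC", "CC(C)C", "CCCC"],
    ],
    "nitro_reduction": [
        ["CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CCC(C)C", "CCCCCC",
         "CC(C)CC", "CCCCCCC", "CCCCCCCC", "CC(C)CCC", "CCCCC(C)C",
         "CCCCCCCCC", "CCC(CC)CC", "CCCCCCCCCC"],
    ],
}

# reserved pools for compounds that trigger rules but have no observed
# reaction (negative-sample generators)
NOISE_POOLS = {
    "dechlorination": [
        ["CC(C)(C)C", "CCCC(C)(C)C", "CC(C)C(C)C", "CCCCCC(C)C",
         "CCC(CC)CCC", "CC(C)(C)CC", "CCCCCCCCCC", "CC(C)C(C)CC",
         "CCC(C)(C)CC", "CCCC(CC)CC", "CC(CC)(CC)C", "CCCCCCC(C)C"],
    ],
    "alcohol_oxidation": [
        ["CCCCCC", "CC(C)CC", "CCCCCCC"],
        ["C(C)CC", "CCCCC", "C(CC)CC"],
    ],
    "ester_hydrolysis": [
        ["CCCCC", "CC(C)CC", "CCCCCC"],
        ["CCCCC", "C(C)CC", "CCCCCC"],
    ],
    "nitro_reduction": [
        ["CC(C)(C)C", "CCCCCCCCC", "CC(C)C(C)C", "CCC(CC)CC",
         "CC(C)(C)CC", "CCCCCCCCCC"],
    ],
}


def _family(family) -> ReactionFamily:
    if isinstance(family, ReactionFamily):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise FixtureError(f"unknown reaction family {family!r}") from None


def build_substrate(family, substituents: Sequence[str]) -> str:
    fam = _family(family)
    if len(substituents) != fam.n_slots:
        raise FixtureError(
            f"{fam.name} expects {fam.n_slots} substituent(s), got "
            f"{len(substituents)}"
        )
    smiles = fam.template.format(*substituents)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FixtureError(
            f"{fam.name}: substituents {substituents!r} give invalid SMILES "
            f"{smiles!r}"
        )
    return canonical_smiles(mol)


def build_reaction(family, substrate_smiles: str, reaction_id: str,
                   strict: bool = True) -> MappedReaction:
    """Apply a family transform to a substrate, producing a mapped reaction."""
    fam = _family(family)
    mol = _mapped(mol_from_smiles(substrate_smiles))
    query = Chem.MolFromSmarts(fam.center_smarts)
    matches = mol.GetSubstructMatches(query)
    if not matches:
        raise FixtureError(
            f"{fam.name}: no reaction site in {substrate_smiles!r}"
        )
    if strict and len(matches) > 1:
        raise FixtureError(
            f"{fam.name}: ambiguous reaction site in {substrate_smiles!r}"
        )
    edited = fam.transform(mol, matches[0])
    product = edited.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise FixtureError(
            f"{fam.name}: transform of {substrate_smiles!r} gives an invalid "
            f"product: {exc}"
        ) from exc
    prods = Chem.GetMolFrags(product, asMols=True)
    rhs = ".".join(Chem.MolToSmiles(p) for p in prods)
    return parse_reaction(f"{Chem.MolToSmiles(mol)}>>{rhs}", reaction_id)


def make_reaction_family(
    family,
    pools: Sequence[Sequence[str]] = None,
    n: int = 5,
    seed: int = 0,
    id_prefix: str = None,
) -> list:
    """n mapped reactions sharing one reaction center, substituents seeded.

    All returned reactions are pairwise fingerprint-identical (validated at
    generation time) and have distinct substrates.
    """
    from .fingerprints import fingerprint_reaction

    fam = _family(family)
    pools = pools if pools is not None else DEFAULT_POOLS[fam.name]
    if n < 1:
        raise FixtureError("n must be >= 1")
    combos = list(itertools.product(*pools))
    if len(combos) < n:
        raise FixtureError(
            f"{fam.name}: only {len(combos)} substituent combinations for "
            f"n={n}"
        )
    rng = np.random.default_rng(seed)
    # distinct combos can collide on the same molecule (e.g. swapped
    # substituents on a symmetric template): draw until n unique substrates
    picked = []
    seen = set()
    for i in rng.permutation(len(combos)):
        substrate = build_substrate(fam, combos[i])
        if substrate in seen:
            continue
        seen.add(substrate)
        picked.append((substrate, combos[i]))
        if len(picked) == n:
            break
    if len(picked) < n:
        raise FixtureError(
            f"{fam.name}: only {len(picked)} unique substrates for n={n}"
        )
    prefix = id_prefix or fam.name
    reactions = []
    for i, (substrate, _) in enumerate(sorted(picked)):
        reactions.append(build_reaction(fam, substrate, f"{prefix}-{i + 1:03d}"))
    keys = {fingerprint_reaction(r).key() for r in reactions}
    if len(keys) != 1:
        raise FixtureError(
            f"{fam.name}: generated reactions do not share one fingerprint"
        )
    return reactions


def make_compounds(family, pools=None, n: int = 5, seed: int = 0) -> list:
    """Substrate-shaped compounds with no observed reaction (noise)."""
    fam = _family(family)
    pools = pools if pools is not None else NOISE_POOLS[fam.name]
    combos = list(itertools.product(*pools))
    if len(combos) < n:
        raise FixtureError(f"{fam.name}: only {len(combos)} noise combinations")
    rng = np.random.default_rng(seed)
    picked = [combos[i] for i in rng.permutation(len(combos))[:n]]
    return sorted(build_substrate(fam, subs) for subs in picked)


def make_screening_compounds(n: int = 200, seed: int = 0) -> list:
    """A diverse compound library for trigger-set screening.

    Combinatorial head-linker-tail molecules (alkanes, alcohols, amines,
    ethers, esters, halides, nitro and aryl compounds), canonicalized,
    deduplicated and seeded.
    """
    heads = ["C", "CC", "CCC", "CCCC", "CC(C)C", "CCC(C)C", "CCCCC",
             "CC(C)CC"]
    linkers = ["", "O", "N", "C(O)", "C(=O)O", "OC(=O)"]
    tails = ["C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C"]
    pool = set()
    for a in heads:
        for link in linkers:
            for b in tails:
                mol = Chem.MolFromSmiles(f"{a}{link}{b}")
                if mol is not None:
                    pool.add(Chem.MolToSmiles(mol))
    for a in heads:
        for extra in (f"Cl{a}", f"{a}[N+](=O)[O-]", f"{a}c1ccccc1",
                      f"OC{a}", f"Clc1ccc({a})cc1"):
            mol = Chem.MolFromSmiles(extra)
            if mol is not None:
                pool.add(Chem.MolToSmiles(mol))
    pool = sorted(pool)
    if len(pool) < n:
        raise FixtureError(f"only {len(pool)} screening compounds available")
    rng = np.random.default_rng(seed)
    picked = [pool[i] for i in rng.permutation(len(pool))[:n]]
    return sorted(picked)


# ---------------------------------------------------------------------------
# corpora
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCorpus:
    """Reactions, their substrates, noise compounds and (optional) pathways."""

    reactions: list
    noise_compounds: list = field(default_factory=list)
    pathways: list = field(default_factory=list)

    @property
    def substrates(self) -> list:
        return sorted({r.substrate_smiles for r in self.reactions})

    @property
    def compounds(self) -> list:
        return sorted(set(self.substrates) | set(self.noise_compounds))

    def observed(self) -> dict:
        from .rules import build_observed_index

        return build_observed_index(self.reactions)


def make_corpus(
    families: Sequence[str] = (
        "dechlorination",
        "alcohol_oxidation",
        "ester_hydrolysis",
        "nitro_reduction",
    ),
    n_per_family: int = 12,
    n_noise_per_family: int = 0,
    seed: int = 0,
) -> SyntheticCorpus:
    """A flat multi-family reaction corpus, optionally with noise compounds.

    Families use mutually exclusive trigger chemistry, so with zero noise
    every compound a rule fires on has observed products (an oracle corpus).
    """
    reactions = []
    noise = []
    for k, name in enumerate(families):
        reactions.extend(
            make_reaction_family(name, n=n_per_family, seed=seed + k)
        )
        if n_noise_per_family:
            noise.extend(
                make_compounds(name, n=n_noise_per_family, seed=seed + 100 + k)
            )
    return SyntheticCorpus(reactions=reactions, noise_compounds=sorted(noise))


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

_CHAIN_STEPS = ["dechlorination", "alcohol_oxidation", "nitro_reduction"]


def _chain_root(depth: int, a: str, b: str) -> str:
    if depth == 1:
        return f"Cl{a}"
    if depth == 2:
        return f"Cl{a}C(O){b}"
    if depth == 3:
        return f"Cl{a}C(O){b}[N+](=O)[O-]"
    raise FixtureError("pathway depth must be 1, 2 or 3")


def make_pathways(
    n: int = 6,
    depth: int = 2,
    branching: int = 1,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> SyntheticCorpus:
    """Rooted pathway graphs whose edges are family reactions.

    Each pathway is a chain (dechlorination, then alcohol oxidation, then
    nitro reduction, truncated to ``depth``); with ``branching`` = 2 the
    root carries two independent reaction sites that both react at
    generation 1.  ``noise_frac`` controls the fraction of compounds that
    trigger rules without any observed reaction.
    """
    if depth < 1:
        raise FixtureError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    pool_a = ["CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CCC(C)C", "CCCCCC",
              "CC(C)CC", "CCCCCCC", "CCCCCCCC"]
    pool_b = ["C", "CC", "CCC", "CCCC", "C(C)C"]
    combos = list(itertools.product(pool_a, pool_b))
    if len(combos) < n:
        raise FixtureError("not enough substituent combinations")
    picked = [combos[i] for i in rng.permutation(len(combos))[:n]]

    pathways = []
    reactions = []
    counter = itertools.count(1)
    for a, b in sorted(picked):
        pid = f"pw-{next(counter):03d}"
        edges = []
        if branching >= 2:
            root = f"Cl{a}C(O){b}[N+](=O)[O-]"
            r1 = build_reaction("dechlorination", canonical_smiles(root),
                                f"{pid}-dechlor", strict=False)
            r2 = build_reaction("nitro_reduction", canonical_smiles(root),
                                f"{pid}-nitro", strict=False)
            child1 = sorted(r1.product_smiles)[0]
            for r in (r1, r2):
                edges.append(
                    (r.substrate_smiles, r.smiles(), sorted(r.product_smiles))
                )
            if depth >= 2:
                r3 = build_reaction("alcohol_oxidation", child1,
                                    f"{pid}-oxid", strict=False)
                edges.append(
                    (r3.substrate_smiles, r3.smiles(), sorted(r3.product_smiles))
                )
                reactions.append(r3)
            reactions.extend([r1, r2])
        else:
            compound = canonical_smiles(_chain_root(depth, a, b))
            for g in range(depth):
                fam = _CHAIN_STEPS[g]
                r = build_reaction(fam, compound, f"{pid}-g{g + 1}", strict=False)
                prods = sorted(r.product_smiles)
                edges.append((r.substrate_smiles, r.smiles(), prods))
                reactions.append(r)
                compound = prods[0]
        pathways.append(PathwayGraph.from_edges(pid, edges))

    n_compounds = len({n_ for p in pathways for n_ in p.graph.nodes})
    noise = []
    if noise_frac > 0:
        n_noise = max(1, round(noise_frac * n_compounds / (1.0 - noise_frac)))
        per = -(-n_noise // 2)
        noise = (
            make_compounds("dechlorination", n=min(per, 12), seed=seed + 11)
            + make_compounds("alcohol_oxidation", n=min(per, 9), seed=seed + 12)
        )[:n_noise]
    corpus = SyntheticCorpus(
        reactions=reactions, noise_compounds=sorted(noise), pathways=pathways
    )
    return corpus


# ---------------------------------------------------------------------------
# engineered fixtures with forced genericity structure
# ---------------------------------------------------------------------------


def genericity_ladder_fixture():
    """A dechlorination group whose tuning states have forced genericities.

    Two observed reactions (PS = 2) and 16 decoy compounds arranged so the
    composite rule's genericity is 8.0 at diameter 0, 4.0 at diameter 1 and
    1.0 at diameter 2: 8 decoys lack a carbon neighbor at the reaction
    center, 6 more lack the second-shell carbon, and 2 survive to diameter
    2.  Returns (reactions, compounds, observed_index).
    """
    from .rules import build_observed_index

    reactions = [
        build_reaction("dechlorination", "CCCCl", "ladder-001"),
        build_reaction("dechlorination", "CCCCCl", "ladder-002"),
    ]
    decoys_d0 = ["CCl", "ClCO", "ClCOC", "ClCN", "ClCNC", "ClCOCC",
                 "ClCNCC", "ClCOC(C)C"]
    decoys_d1 = ["ClCC", "ClCCO", "ClCCN", "ClCCOC", "ClCCNC", "ClCCF"]
    decoys_d2 = ["ClCCCO", "ClCCCN"]
    compounds = sorted(
        {r.substrate_smiles for r in reactions}
        | {canonical_smiles(s) for s in decoys_d0 + decoys_d1 + decoys_d2}
    )
    return reactions, compounds, build_observed_index(reactions)


def scan_fixture(seed: int = 0):
    """A corpus engineered so the genericity scan selects level 5.

    Members are primary chlorides Cl-CH2CH2CH2-R.  Three decoy strata force
    the tuned states apart: a large stratum of short/branched chlorides
    (feature-wise close to the members) keeps genericity high at diameters
    0-1, so generic targets train against inseparable negatives; an
    aromatic stratum survives to diameter 2 with genericity near 5 and is
    cleanly separable by structural keys; nothing survives diameter 3, and
    the members' tails diverge there, so very specific targets stop
    covering held-out substrates.  Returns (reactions, compounds).
    """
    members = [
        "ClCCC" + t
        for t in ("CC", "CCC", "CCCC", "CO", "COC", "OC", "OCC", "OCCC")
    ]
    reactions = [
        build_reaction("dechlorination", canonical_smiles(s),
                       f"scan-{i + 1:03d}")
        for i, s in enumerate(members)
    ]
    # short/branched chlorides: no Cl-C-C-C path, so they fire only at
    # diameters 0-1; feature-wise they share the members' fragment
    # vocabulary (chains, ethers, amines)
    heads = ("", "(C)", "(C)(C)")
    tails = ("C", "CF", "CO", "CN", "COC", "CNC", "COCC", "CNCC", "COCCC",
             "CNCCC", "COC(C)C", "CNC(C)C", "COCO", "CNCO", "COCN", "CNCN",
             "COCCO", "CNCCO")
    hard = []
    for head in heads:
        for tail in tails:
            smiles = f"ClC{head}{tail}"
            if Chem.MolFromSmiles(smiles) is not None:
                hard.append(smiles)
    # aromatic-tailed chlorides: survive to diameter 2 (Cl-C-C-C present)
    # but not 3 (aromatic frontier atom), and carry a clean structural-key
    # signature no member has
    subs = ("", "C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C", "CCC(C)C",
            "CCCCC", "CCCCCC", "CCCCC(C)C", "CCCCCCC")
    aromatic = [f"ClCCCc1ccc({s})cc1" if s else "ClCCCc1ccccc1" for s in subs]
    aromatic += [f"ClCCCc1cccc({s})c1" for s in subs[1:]]
    compounds = sorted(
        {r.substrate_smiles for r in reactions}
        | {canonical_smiles(s) for s in hard + aromatic}
    )
    return reactions, compounds
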