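"""Precision/recall evaluation of rule-based transformation-product prediction.

Single-generation evaluation scores predictions reaction by reaction: for
every threshold t, the products of all rules whose predicted probability is
at least t are compared, as canonical SMILES sets, with the observed
products of each test substrate.  TP and FP count correctly and falsely
predicted products; FN counts only products documented in the dataset that
were not predicted (undetected true products cannot be known).

Multi-generation evaluation scores whole pathways: prediction proceeds
breadth first from the root compounds up to the reference pathway's maximum
generation, products at generation g carry weight w**(g-1), and two kinds
of unobserved predictions are exempt from the false-positive count —
intermediates that lead to correct downstream products, and co-products
formed in the same reaction as a correct product.

The area under the curve is the trapezoidal area under the recall-ordered
precision-recall curve.  Precision at zero predictions is 1.0 by
convention (logged once), so curve aggregation never divides by zero.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .chem import canonical_smiles
from .cluster import cluster
from .ml import EccModel, build_samples, train
from .pathways import PathwayGraph
from .rules import RuleSet, build_observed_index, generate_ruleset

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(1.0, 0.0, 101), 6))
DEFAULT_GENERICITY_LEVELS = (0, 1, 5, 10, 20, 50)


@dataclass
class EvalReport:
    thresholds: list
    precision: list
    recall: list
    auc: float
    repetitions: int = 1
    split_seeds: list = field(default_factory=list)
    per_rep_auc: list = field(default_factory=list)

    def to_rows(self) -> list:
        return [
            {"threshold": t, "precision": p, "recall": r}
            for t, p, r in zip(self.thresholds, self.precision, self.recall)
        ]


def pr_auc(precision: Sequence[float], recall: Sequence[float]) -> float:
    """Trapezoidal area under the recall-ordered precision-recall curve."""
    pts = sorted(zip(recall, precision))
    rs = [0.0] + [r for r, _ in pts]
    ps = [pts[0][1]] + [p for _, p in pts]
    return float(np.trapezoid(ps, rs))


def _precision(tp: float, fp: float) -> float:
    if tp + fp == 0:
        return 1.0  # no predictions made: convention
    return tp / (tp + fp)


def _recall(tp: float, fn: float) -> float:
    if tp + fn == 0:
        return 0.0
    return tp / (tp + fn)


def model_scorer(model: EccModel, ruleset: RuleSet) -> Callable:
    """Probability scorer backed by a trained ECC model (memoized)."""
    cache: dict = {}

    def score(smiles: str) -> dict:
        if smiles not in cache:
            probs = model.predict_proba(smiles, ruleset)
            cache[smiles] = dict(zip(model.rule_ids, probs))
        return cache[smiles]

    return score


def oracle_scorer(ruleset: RuleSet, observed: Mapping[str, set]) -> Callable:
    """Probability 1 for rules whose prediction is observed, 0 otherwise."""

    def score(smiles: str) -> dict:
        out = {}
        for rule in ruleset.rule_list:
            outcomes = rule.apply(smiles)
            ok = any(o in observed.get(smiles, ()) for o in outcomes)
            out[rule.group_id] = 1.0 if ok else 0.0
        return out

    return score


# ---------------------------------------------------------------------------
# single-generation (reaction-level) evaluation
# ---------------------------------------------------------------------------


def single_gen(
    scorer: Callable,
    ruleset: RuleSet,
    test_reactions: Sequence,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    test_compounds: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Reaction-level precision/recall over a probability-threshold sweep.

    Evaluation is per test compound: predictions on a compound without any
    documented reaction count entirely as false positives (its true
    products are simply unknown), mirroring compound-wise train/test
    splitting.  ``test_compounds`` defaults to the substrates of the test
    reactions.
    """
    observed_by_sub: dict = defaultdict(set)
    for r in test_reactions:
        observed_by_sub[r.substrate_smiles] |= set(r.product_smiles)
    if test_compounds is not None:
        for c in test_compounds:
            observed_by_sub.setdefault(canonical_smiles(c), set())

    # rule applications and scores are threshold-independent
    per_sub = []
    for sub, obs in sorted(observed_by_sub.items()):
        probs = scorer(sub)
        preds = []
        for rule in ruleset.rule_list:
            outcomes = rule.apply(sub)
            if outcomes:
                prods = set().union(*outcomes)
                preds.append((probs.get(rule.group_id, 0.0), prods))
        per_sub.append((obs, preds))

    precision, recall = [], []
    for t in thresholds:
        tp = fp = fn = 0
        for obs, preds in per_sub:
            predicted = set()
            for p, prods in preds:
                if p >= t:
                    predicted |= prods
            tp += len(predicted & obs)
            fp += len(predicted - obs)
            fn += len(obs - predicted)
        precision.append(_precision(tp, fp))
        recall.append(_recall(tp, fn))
    return EvalReport(
        thresholds=list(thresholds),
        precision=precision,
        recall=recall,
        auc=pr_auc(precision, recall),
    )


# ---------------------------------------------------------------------------
# multi-generation (pathway-level) evaluation
# ---------------------------------------------------------------------------


def _predict_pathway(scorer, ruleset, pathway: PathwayGraph, threshold, max_nodes):
    """Breadth-first expansion from the roots up to the observed depth.

    Returns (depth of each predicted compound, predicted edges, reaction
    outcome instances as (parent, frozenset-of-products) pairs).
    """
    max_depth = pathway.max_generation
    roots = pathway.roots
    depth = {r: 0 for r in roots}
    edges = []
    outcomes_log = []
    frontier = list(roots)
    while frontier:
        nxt = []
        for node in frontier:
            if depth[node] >= max_depth:
                continue
            probs = scorer(node)
            for rule in ruleset.rule_list:
                if probs.get(rule.group_id, 0.0) < threshold:
                    continue
                for outcome in rule.apply(node):
                    outcomes_log.append((node, outcome))
                    for prod in outcome:
                        edges.append((node, prod))
                        if prod not in depth:
                            depth[prod] = depth[node] + 1
                            nxt.append(prod)
        if len(depth) > max_nodes:
            logger.warning(
                "pathway %s: prediction truncated at %d nodes",
                pathway.pathway_id,
                max_nodes,
            )
            break
        frontier = nxt
    return depth, edges, outcomes_log


def _pathway_counts(
    scorer,
    ruleset,
    pathway: PathwayGraph,
    threshold,
    gen_weight,
    exempt_intermediates,
    exempt_coproducts,
    max_nodes,
):
    gens = pathway.generations()
    observed = {n: g for n, g in gens.items() if g > 0}
    depth, edges, outcomes_log = _predict_pathway(
        scorer, ruleset, pathway, threshold, max_nodes
    )
    predicted = {n: d for n, d in depth.items() if d > 0 and n not in pathway.roots}

    matched = set(observed) & set(predicted)
    tp = sum(gen_weight ** (observed[n] - 1) for n in matched)
    fn = sum(gen_weight ** (observed[n] - 1) for n in observed if n not in matched)

    # reverse reachability from matched nodes, for intermediate credit
    leads_to_match = set(matched)
    if exempt_intermediates:
        parents = defaultdict(set)
        for a, b in edges:
            parents[b].add(a)
        stack = list(matched)
        while stack:
            node = stack.pop()
            for par in parents[node]:
                if par not in leads_to_match:
                    leads_to_match.add(par)
                    stack.append(par)

    coproduct_ok = set()
    if exempt_coproducts:
        for _, outcome in outcomes_log:
            if any(p in matched for p in outcome):
                coproduct_ok |= {p for p in outcome if p not in matched}

    fp = 0.0
    for node, d in predicted.items():
        if node in matched:
            continue
        if exempt_intermediates and node in leads_to_match:
            continue
        if exempt_coproducts and node in coproduct_ok:
            continue
        fp += gen_weight ** (d - 1)
    return tp, fp, fn


def multi_gen(
    scorer: Callable,
    ruleset: RuleSet,
    pathways: Sequence[PathwayGraph],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    gen_weight: float = 0.5,
    exempt_intermediates: bool = True,
    exempt_coproducts: bool = True,
    max_nodes: int = 2000,
) -> EvalReport:
    """Pathway-level precision/recall with generation discounting.

    Products at generation g weigh ``gen_weight**(g-1)``; unobserved
    intermediates leading to correct downstream products and co-products of
    correct products contribute nothing to FP (both exemptions can be
    switched off, in which case depth-1 pathways at weight 1 reproduce
    single-generation evaluation exactly).
    """
    for p in pathways:
        p.validate()
    precision, recall = [], []
    for t in thresholds:
        tp = fp = fn = 0.0
        for pathway in pathways:
            ptp, pfp, pfn = _pathway_counts(
                scorer,
                ruleset,
                pathway,
                t,
                gen_weight,
                exempt_intermediates,
                exempt_coproducts,
                max_nodes,
            )
            tp, fp, fn = tp + ptp, fp + pfp, fn + pfn
        precision.append(_precision(tp, fp))
        recall.append(_recall(tp, fn))
    return EvalReport(
        thresholds=list(thresholds),
        precision=precision,
        recall=recall,
        auc=pr_auc(precision, recall),
    )


# ---------------------------------------------------------------------------
# repeated train/test splits and the genericity scan
# ---------------------------------------------------------------------------


def _split_compounds(compounds, train_frac, rng):
    compounds = sorted(compounds)
    if len(compounds) < 2:
        raise ValueError("need at least 2 compounds to split")
    n_train = max(1, min(len(compounds) - 1, round(train_frac * len(compounds))))
    perm = rng.permutation(len(compounds))
    train = {compounds[i] for i in perm[:n_train]}
    test = {compounds[i] for i in perm[n_train:]}
    return train, test


def _pipeline(
    train_reactions,
    train_compounds,
    target_genericity,
    functional_groups,
    max_diameter,
    n_chains,
    model_seed,
):
    observed = build_observed_index(train_reactions)
    groups = cluster(train_reactions, functional_groups)
    ruleset = generate_ruleset(
        groups,
        target_genericity,
        sorted(train_compounds),
        observed,
        functional_groups,
        max_diameter,
    )
    samples = build_samples(sorted(train_compounds), ruleset, observed)
    model = train(samples, n_chains=n_chains, seed=model_seed)
    return ruleset, model


def repeated_split_eval(
    reactions: Sequence,
    train_frac: float = 0.8,
    reps: int = 100,
    seed: int = 0,
    *,
    target_genericity: float = 5.0,
    functional_groups: Sequence = (),
    extra_compounds: Sequence[str] = (),
    max_diameter: int = 8,
    n_chains: int = 10,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    pathways: Optional[Sequence[PathwayGraph]] = None,
    gen_weight: float = 0.5,
) -> EvalReport:
    """Full pipeline under repeated compound-level train/test splits.

    Splits are by compound, so all reactions of a substrate stay on one
    side.  Per repetition: cluster the training reactions, generate rules
    at the target genericity, train an ECC, then evaluate on the held-out
    reactions (or, when ``pathways`` is given, on pathways rooted at
    held-out compounds).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    all_compounds = {r.substrate_smiles for r in reactions} | {
        canonical_smiles(c) for c in extra_compounds
    }
    curves_p, curves_r, aucs, seeds = [], [], [], []
    for rep in range(reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        split_rng = np.random.default_rng(rep_seed)
        train_set, test_set = _split_compounds(all_compounds, train_frac, split_rng)
        train_rxns = [r for r in reactions if r.substrate_smiles in train_set]
        test_rxns = [r for r in reactions if r.substrate_smiles in test_set]
        if not train_rxns or (pathways is None and not test_rxns):
            seeds.append(rep_seed)
            continue
        ruleset, model = _pipeline(
            train_rxns,
            train_set,
            target_genericity,
            functional_groups,
            max_diameter,
            n_chains,
            rep_seed,
        )
        scorer = model_scorer(model, ruleset)
        if pathways is None:
            report = single_gen(
                scorer, ruleset, test_rxns, thresholds, test_compounds=test_set
            )
        else:
            test_pathways = [p for p in pathways if set(p.roots) & test_set]
            if not test_pathways:
                seeds.append(rep_seed)
                continue
            report = multi_gen(
                scorer, ruleset, test_pathways, thresholds, gen_weight
            )
        curves_p.append(report.precision)
        curves_r.append(report.recall)
        aucs.append(report.auc)
        seeds.append(rep_seed)
    if not aucs:
        raise ValueError("no repetition produced a testable split")
    mean_p = list(np.mean(curves_p, axis=0))
    mean_r = list(np.mean(curves_r, axis=0))
    return EvalReport(
        thresholds=list(thresholds),
        precision=mean_p,
        recall=mean_r,
        auc=float(np.mean(aucs)),
        repetitions=len(aucs),
        split_seeds=seeds,
        per_rep_auc=[float(a) for a in aucs],
    )


@dataclass
class GenericityScanResult:
    levels: list
    mean_probability: dict  # level -> mean over reps
    sd_probability: dict
    best_level: float


def genericity_scan(
    reactions: Sequence,
    levels: Sequence[float] = DEFAULT_GENERICITY_LEVELS,
    train_frac: float = 0.8,
    reps: int = 5,
    seed: int = 0,
    *,
    pathways: Optional[Sequence[PathwayGraph]] = None,
    functional_groups: Sequence = (),
    extra_compounds: Sequence[str] = (),
    max_diameter: int = 8,
    n_chains: int = 10,
) -> GenericityScanResult:
    """Mean predicted probability of observed test reactions, per genericity.

    For each target level, rules are regenerated at that genericity, a model
    is trained on the training compounds, and each held-out test reaction
    contributes the predicted probability of the rule that reproduces it
    (zero when no rule covers it).  The level with the highest mean is the
    selected optimum.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    reactions = list(reactions)
    if pathways:
        known = {r.reaction_id for r in reactions}
        for p in pathways:
            reactions.extend(
                r for r in p.all_reactions() if r.reaction_id not in known
            )
    rng = np.random.default_rng(seed)
    all_compounds = {r.substrate_smiles for r in reactions} | {
        canonical_smiles(c) for c in extra_compounds
    }
    per_level: dict = {lv: [] for lv in levels}
    for rep in range(reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        split_rng = np.random.default_rng(rep_seed)
        train_set, test_set = _split_compounds(all_compounds, train_frac, split_rng)
        train_rxns = [r for r in reactions if r.substrate_smiles in train_set]
        test_rxns = [r for r in reactions if r.substrate_smiles in test_set]
        if not train_rxns or not test_rxns:
            continue
        for level in levels:
            ruleset, model = _pipeline(
                train_rxns,
                train_set,
                level,
                functional_groups,
                max_diameter,
                n_chains,
                rep_seed,
            )
            scorer = model_scorer(model, ruleset)
            probs = []
            for r in test_rxns:
                covering = [
                    rule.group_id for rule in ruleset.rule_list if rule.covers(r)
                ]
                if not covering:
                    probs.append(0.0)
                    continue
                scores = scorer(r.substrate_smiles)
                probs.append(max(scores.get(g, 0.0) for g in covering))
            per_level[level].append(float(np.mean(probs)))
    if not any(per_level.values()):
        raise ValueError("no repetition produced a testable split")
    mean = {lv: float(np.mean(v)) for lv, v in per_level.items() if v}
    sd = {
        lv: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        for lv, v in per_level.items()
        if v
    }
    level_order = list(levels)
    best = max(mean, key=lambda lv: (mean[lv], -level_order.index(lv)))
    return GenericityScanResult(
        levels=list(levels),
        mean_probability=mean,
        sd_probability=sd,
        best_level=best,
    )
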