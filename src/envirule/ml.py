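"""Multi-label training data and ensembles of classifier chains.

Pathway prediction is reduced to multi-label classification: for each
composite rule (label) a classifier learns whether the rule, when it fires
on a compound, yields experimentally observed products.  A compound on
which a rule fires with observed products is a positive sample (PS) for
that rule's label; firing without observed products makes it a negative
sample (NS); a compound the rule does not fire on carries no label for it.

Features are MACCS structural keys concatenated with the per-rule trigger
bits.  The ensemble of classifier chains (ECC) trains, per chain, one base
classifier per label in a seeded random label order, feeding earlier
labels' values to later classifiers; at prediction time earlier labels'
thresholded predictions are fed forward and probabilities are averaged over
chains.  Base classifiers are L2-regularized logistic regressions; labels
without both a positive and a negative example fall back to a constant
(Laplace-smoothed positive-rate) probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from sklearn.linear_model import LogisticRegression

from .chem import canonical_smiles, mol_from_smiles
from .rules import RuleSet

MACCS_BITS = 167  # standard public key set (bit 0 unused), zero-padded block

_FEATURE_CACHE: dict = {}


def maccs_features(compound) -> np.ndarray:
    """MACCS structural-key bit vector for one compound."""
    smiles = compound if isinstance(compound, str) else canonical_smiles(compound)
    cached = _FEATURE_CACHE.get(smiles)
    if cached is None:
        mol = mol_from_smiles(smiles) if isinstance(compound, str) else compound
        bv = MACCSkeys.GenMACCSKeys(mol)
        cached = np.zeros(MACCS_BITS, dtype=np.float64)
        for bit in bv.GetOnBits():
            cached[bit] = 1.0
        _FEATURE_CACHE[smiles] = cached
    return cached


@dataclass
class TrainingSamples:
    """PS/NS multi-label matrix over a compound set.

    ``labels[i, j]`` is 1.0 (positive), 0.0 (negative) or NaN (rule j not
    triggered on compound i); ``triggers`` holds the corresponding 0/1
    trigger bits, which are also part of the feature block.
    """

    compounds: list
    rule_ids: list
    structural: np.ndarray  # (n, MACCS_BITS)
    triggers: np.ndarray  # (n, m)
    labels: np.ndarray  # (n, m), NaN = missing

    @property
    def features(self) -> np.ndarray:
        return np.hstack([self.structural, self.triggers])

    def label_counts(self, j: int):
        col = self.labels[:, j]
        defined = ~np.isnan(col)
        pos = int(np.sum(col[defined] == 1.0))
        neg = int(np.sum(col[defined] == 0.0))
        return pos, neg


def build_samples(
    compounds: Sequence[str],
    ruleset: RuleSet,
    observed: Mapping[str, set],
) -> TrainingSamples:
    """One sample per compound; PS/NS assignment per rule.

    A rule's label is positive when at least one of its predicted product
    sets matches an observed reaction of the compound, negative when the
    rule triggers with no observed match, and missing when it does not
    trigger.  Compounds triggering no rule are retained with all-missing
    labels.
    """
    canon = [canonical_smiles(c) for c in compounds]
    rules = ruleset.rule_list
    n, m = len(canon), len(rules)
    structural = np.zeros((n, MACCS_BITS))
    triggers = np.zeros((n, m))
    labels = np.full((n, m), np.nan)
    for i, smiles in enumerate(canon):
        structural[i] = maccs_features(smiles)
        obs = observed.get(smiles, ())
        for j, rule in enumerate(rules):
            outcomes = rule.apply(smiles)
            if not outcomes:
                continue
            triggers[i, j] = 1.0
            labels[i, j] = 1.0 if any(o in obs for o in outcomes) else 0.0
    return TrainingSamples(
        compounds=canon,
        rule_ids=[r.group_id for r in rules],
        structural=structural,
        triggers=triggers,
        labels=labels,
    )


@dataclass
class _ChainLink:
    kind: str  # "model" | "constant"
    model: Optional[LogisticRegression] = None
    constant: float = 0.5


@dataclass
class EccModel:
    """Ensemble of classifier chains over rule labels.

    Reproducible for a fixed seed: chain label orders and base-classifier
    seeds all derive from ``seed``.
    """

    rule_ids: list
    n_chains: int
    seed: int
    chains: list = field(default_factory=list)  # [(order, [_ChainLink])]

    def predict_proba(self, compound, ruleset: Optional[RuleSet] = None) -> np.ndarray:
        feats = self._compound_features(compound, ruleset)
        return self.predict_proba_features(feats)

    def _compound_features(self, compound, ruleset):
        if ruleset is None:
            raise ValueError("ruleset required to featurize a raw compound")
        smiles = compound if isinstance(compound, str) else canonical_smiles(compound)
        trig = np.array(
            [1.0 if rule.triggers(smiles) else 0.0 for rule in ruleset.rule_list]
        )
        return np.concatenate([maccs_features(smiles), trig])

    def predict_proba_features(self, features: np.ndarray) -> np.ndarray:
        m = len(self.rule_ids)
        acc = np.zeros(m)
        for order, links in self.chains:
            probs = np.zeros(m)
            chain_feats = np.zeros(m)
            for pos, j in enumerate(order):
                link = links[pos]
                if link.kind == "constant":
                    p = link.constant
                else:
                    x = np.concatenate([features, chain_feats[order[:pos]]])
                    p = float(link.model.predict_proba(x[None, :])[0, 1])
                probs[j] = p
                chain_feats[j] = 1.0 if p >= 0.5 else 0.0
            acc += probs
        return acc / len(self.chains)


def train(
    samples: TrainingSamples,
    n_chains: int = 10,
    seed: int = 0,
    c_reg: float = 1.0,
) -> EccModel:
    """Fit an ECC on PS/NS samples.

    Rows with a missing label are excluded from that label's loss; earlier
    labels in a chain enter later classifiers as 0/1 features (true labels
    during training, thresholded predictions at inference).
    """
    if samples.labels.size == 0 or len(samples.compounds) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    X = samples.features
    Y = samples.labels
    m = Y.shape[1]
    model = EccModel(rule_ids=list(samples.rule_ids), n_chains=n_chains, seed=seed)
    label_feats = np.nan_to_num(Y, nan=0.0)
    for _ in range(n_chains):
        order = list(rng.permutation(m))
        links = []
        for pos, j in enumerate(order):
            pos_n, neg_n = samples.label_counts(j)
            if pos_n < 1 or neg_n < 1:
                # one-class label: no discriminative signal, uninformative
                # constant probability
                links.append(_ChainLink(kind="constant", constant=0.5))
                continue
            defined = ~np.isnan(Y[:, j])
            Xj = np.hstack([X[defined], label_feats[defined][:, order[:pos]]])
            yj = Y[defined, j]
            # default penalty is L2; C controls its strength
            clf = LogisticRegression(
                C=c_reg,
                max_iter=2000,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            clf.fit(Xj, yj)
            links.append(_ChainLink(kind="model", model=clf))
        model.chains.append((order, links))
    return model
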