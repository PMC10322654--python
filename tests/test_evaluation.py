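"""Single-gen and multi-gen precision/recall, splits and the genericity scan."""

import numpy as np
import pytest

from envirule.chem import canonical_smiles
from envirule.evaluation import (
    DEFAULT_GENERICITY_LEVELS,
    genericity_scan,
    model_scorer,
    multi_gen,
    oracle_scorer,
    pr_auc,
    repeated_split_eval,
    single_gen,
)
from envirule.pathways import PathwayGraph
from envirule.synthetic import build_reaction, make_corpus, make_pathways

THRESHOLDS = tuple(np.linspace(1.0, 0.0, 21))


class _StubRule:
    """Fixed compound -> product-set mapping standing in for a SMIRKS rule."""

    def __init__(self, group_id, mapping):
        self.group_id = group_id
        self._mapping = {
            canonical_smiles(k): frozenset(
                {frozenset(canonical_smiles(p) for p in v)}
            )
            for k, v in mapping.items()
        }

    def apply(self, smiles):
        return self._mapping.get(canonical_smiles(smiles), frozenset())

    def triggers(self, smiles):
        return bool(self.apply(smiles))


class _StubRuleSet:
    def __init__(self, rules):
        self.rule_list = rules


def _constant_scorer(value=1.0):
    return lambda smiles: {"r1": value, "r2": value, "r3": value}


class TestSingleGen:
    def test_precision_recall_from_known_counts(self):
        # one substrate, 4 observed products, rule predicting 3 of them
        # plus 1 wrong: TP=3, FP=1, FN=1 -> precision = recall = 0.75
        observed = ["CCO", "CCN", "CCC", "CC=O"]
        predicted = ["CCO", "CCN", "CCC", "CCCl"]
        rxns = [
            # observed reaction per product, same substrate
            type(
                "R",
                (),
                {
                    "substrate_smiles": canonical_smiles("CCCCCCO"),
                    "product_smiles": frozenset({canonical_smiles(p)}),
                },
            )()
            for p in observed
        ]
        ruleset = _StubRuleSet(
            [_StubRule("r1", {"CCCCCCO": predicted})]
        )
        report = single_gen(_constant_scorer(), ruleset, rxns, THRESHOLDS)
        assert report.precision[-1] == pytest.approx(0.75)
        assert report.recall[-1] == pytest.approx(0.75)

    def test_model_predicting_nothing_uses_the_degenerate_convention(self):
        rxns = [
            type(
                "R",
                (),
                {
                    "substrate_smiles": canonical_smiles("CCO"),
                    "product_smiles": frozenset({canonical_smiles("CC=O")}),
                },
            )()
        ]
        ruleset = _StubRuleSet([_StubRule("r1", {})])
        report = single_gen(_constant_scorer(0.0), ruleset, rxns, THRESHOLDS)
        assert all(p == 1.0 for p in report.precision)
        assert all(r == 0.0 for r in report.recall)
        assert report.auc == 0.0

    def test_oracle_model_on_fixtures_is_perfect(self, corpus, corpus_ruleset):
        scorer = oracle_scorer(corpus_ruleset, corpus.observed())
        report = single_gen(
            scorer, corpus_ruleset, corpus.reactions, THRESHOLDS
        )
        assert report.auc == pytest.approx(1.0)
        assert all(p == 1.0 for p in report.precision)

    def test_recall_is_non_increasing_in_threshold(self, corpus,
                                                   corpus_ruleset):
        scorer = oracle_scorer(corpus_ruleset, corpus.observed())
        report = single_gen(scorer, corpus_ruleset, corpus.reactions,
                            THRESHOLDS)
        # thresholds descend, so recall must be non-decreasing along the list
        assert all(
            r2 >= r1 - 1e-12
            for r1, r2 in zip(report.recall, report.recall[1:])
        )


class TestMultiGen:
    def _toy(self):
        """Observed A -> B -> C; model predicts A -> X -> C."""
        A, B, C, X = "CCCCO", "CCCC=O", "CCC=O", "CCCC"
        pathway = PathwayGraph.from_edges(
            "toy",
            [(A, f"{A}>>{B}", [B]), (B, f"{B}>>{C}", [C])],
        )
        ruleset = _StubRuleSet(
            [
                _StubRule("r1", {A: [X]}),
                _StubRule("r2", {X: [C]}),
            ]
        )
        scorer = lambda smiles: {"r1": 1.0, "r2": 1.0}
        return pathway, ruleset, scorer

    def test_intermediate_credit_toy_matches_hand_computation(self):
        # with w = 0.5: C matched at generation 2 (weight 0.5), B missed at
        # generation 1 (weight 1), X exempt because it leads to C:
        # precision = 0.5/0.5 = 1, recall = 0.5/1.5 = 1/3
        pathway, ruleset, scorer = self._toy()
        report = multi_gen(
            scorer, ruleset, [pathway], THRESHOLDS, gen_weight=0.5
        )
        assert report.precision[-1] == pytest.approx(1.0)
        assert report.recall[-1] == pytest.approx(1.0 / 3.0)
        assert report.auc == pytest.approx(1.0 / 3.0)

    def test_unproductive_intermediate_is_punished(self):
        pathway, ruleset, scorer = self._toy()
        report = multi_gen(
            scorer,
            ruleset,
            [pathway],
            THRESHOLDS,
            gen_weight=0.5,
            exempt_intermediates=False,
        )
        # X now counts as FP with weight 1
        assert report.precision[-1] == pytest.approx(0.5 / 1.5)

    def test_coproduct_of_a_correct_product_is_exempt(self):
        # hydrolysis producing an observed acid plus an unobserved
        # co-product: the co-product contributes nothing to FP
        A = "CCC(=O)OCC"
        acid, alcohol = "CCC(=O)O", "CCO"
        pathway = PathwayGraph.from_edges(
            "co", [(A, f"{A}>>{acid}", [acid])]
        )
        ruleset = _StubRuleSet([_StubRule("r1", {A: [acid, alcohol]})])
        scorer = lambda smiles: {"r1": 1.0}
        report = multi_gen(scorer, ruleset, [pathway], THRESHOLDS)
        assert report.precision[-1] == 1.0
        off = multi_gen(
            scorer, ruleset, [pathway], THRESHOLDS, exempt_coproducts=False
        )
        assert off.precision[-1] == pytest.approx(0.5)

    def test_depth_one_pathways_reduce_to_single_gen(self, fgs):
        corpus = make_pathways(n=5, depth=1, seed=9)
        from envirule.cluster import cluster
        from envirule.rules import generate_ruleset

        ruleset = generate_ruleset(
            cluster(corpus.reactions, fgs),
            5.0,
            sorted({r.substrate_smiles for r in corpus.reactions}),
            corpus.observed(),
            fgs,
        )
        scorer = oracle_scorer(ruleset, corpus.observed())
        mg = multi_gen(
            scorer,
            ruleset,
            corpus.pathways,
            THRESHOLDS,
            gen_weight=1.0,
            exempt_intermediates=False,
            exempt_coproducts=False,
        )
        sg = single_gen(scorer, ruleset, corpus.reactions, THRESHOLDS)
        assert mg.precision == sg.precision
        assert mg.recall == sg.recall
        assert mg.auc == sg.auc

    def test_weighted_observed_mass_is_conserved(self):
        # TP + FN always equals the total weighted observed nodes
        pathway, ruleset, scorer = self._toy()
        from envirule.evaluation import _pathway_counts

        for t in (0.0, 0.5, 2.0):
            tp, fp, fn = _pathway_counts(
                scorer, ruleset, pathway, t, 0.5, True, True, 1000
            )
            assert tp + fn == pytest.approx(1.0 + 0.5)

    def test_cyclic_pathway_is_rejected(self):
        import networkx as nx

        g = nx.DiGraph([("A", "B"), ("B", "A")])
        p = PathwayGraph(pathway_id="cyc", graph=g, reactions={})
        from envirule.pathways import PathwayCycleError

        with pytest.raises(PathwayCycleError):
            p.validate()


class TestRepeatedSplitEval:
    def test_split_sizes_and_reproducibility(self, corpus, fgs):
        r1 = repeated_split_eval(
            corpus.reactions, reps=2, seed=5,
            target_genericity=5.0, functional_groups=fgs, n_chains=2,
        )
        r2 = repeated_split_eval(
            corpus.reactions, reps=2, seed=5,
            target_genericity=5.0, functional_groups=fgs, n_chains=2,
        )
        assert r1.split_seeds == r2.split_seeds
        assert r1.per_rep_auc == r2.per_rep_auc

    def test_too_few_compounds_is_an_error(self, fgs):
        r = build_reaction("dechlorination", "CCCCl", "solo")
        with pytest.raises(ValueError):
            repeated_split_eval([r], reps=1, seed=0, functional_groups=fgs)

    def test_oracle_corpus_reaches_auc_one(self, corpus, fgs):
        report = repeated_split_eval(
            corpus.reactions, reps=3, seed=5,
            target_genericity=5.0, functional_groups=fgs, n_chains=2,
        )
        assert report.auc == pytest.approx(1.0)


class TestRandomModelSanity:
    def test_random_probabilities_track_the_positive_rate(self, corpus,
                                                          corpus_ruleset):
        # a model emitting uniform random probabilities should land near
        # the fraction of predicted products that are correct
        observed = corpus.observed()
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cache = {}

            def scorer(smiles):
                if smiles not in cache:
                    cache[smiles] = {
                        r.group_id: float(rng.uniform())
                        for r in corpus_ruleset.rule_list
                    }
                return cache[smiles]

            report = single_gen(
                scorer, corpus_ruleset, corpus.reactions, THRESHOLDS
            )
            aucs.append(report.auc)
        # on the oracle corpus every prediction is correct, so the random
        # model trades recall only; positive-product rate is 1
        assert 0.6 <= float(np.mean(aucs)) <= 1.0


class TestGenericityScan:
    def test_default_level_grid(self):
        assert tuple(DEFAULT_GENERICITY_LEVELS) == (0, 1, 5, 10, 20, 50)

    def test_single_level_is_trivially_best(self, corpus, fgs):
        res = genericity_scan(
            corpus.reactions, levels=(5,), reps=2, seed=3,
            functional_groups=fgs, n_chains=2,
        )
        assert res.best_level == 5

    def test_scan_is_reproducible(self, corpus, fgs):
        a = genericity_scan(
            corpus.reactions, levels=(0, 5), reps=2, seed=3,
            functional_groups=fgs, n_chains=2,
        )
        b = genericity_scan(
            corpus.reactions, levels=(0, 5), reps=2, seed=3,
            functional_groups=fgs, n_chains=2,
        )
        assert a.mean_probability == b.mean_probability


class TestPrAuc:
    def test_perfect_curve_integrates_to_one(self):
        assert pr_auc([1.0, 1.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_empty_prediction_curve_integrates_to_zero(self):
        assert pr_auc([1.0, 1.0], [0.0, 0.0]) == 0.0
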