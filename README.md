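# envirule

Automatic extraction, generalization and incremental updating of
biotransformation reaction rules (SMIRKS), with the machine-learning
evaluation stack used to pick the right level of rule genericity for
transformation-product prediction.

## The problem

Microbial biotransformation of organic contaminants is documented as
pathways: a parent compound, its observed transformation products, and the
reactions connecting them.  Predicting unseen transformation products is
usually done with *reaction rules* — SMARTS/SMIRKS patterns describing
which substructure reacts and how.  Hand-curated rules age badly as
databases grow: new reaction types are missing, and existing rules are
over- or under-generalized.  This package mines rules automatically from
reaction collections and tunes how general each rule is against the
downstream prediction task:

1. **Reaction clustering.** Each single-substrate reaction, with a validated
   heavy-atom atom–atom mapping, is reduced to its *reaction center* —
   changed bonds, changed atoms, and any configured functional group a
   change touches — and encoded as three exact descriptor multisets (bond
   formation/cleavage, bond-order change, center atoms).  Reactions are
   grouped iff their fingerprints have Tanimoto similarity exactly 1.0,
   which for multisets is plain equality.  Groups with ≥ 2 members go to
   rule generation.
2. **Rule generation.** Per group, the center is expanded breadth first to
   a diameter *d*; substituent environments become recursive SMARTS on the
   center atoms, and member substrates are combined into the fewest simple
   rules that never pair two substituents unseen in any one reaction.  The
   composite rule's **genericity** is the negative-to-positive sample
   ratio NS/PS: over a compound set, PS counts compounds where the rule
   fires and a predicted product set matches an observed reaction, NS
   counts compounds where it fires without a match.  The (diameter,
   explicit-hydrogen) state is tuned until NS/PS is as close as possible
   to a target.
3. **Reaction adding.** New reactions join the stored group with an
   identical fingerprint, or found new groups; only touched rules are
   regenerated.  The result is provably equivalent to re-clustering
   everything from scratch.
4. **Prediction models and evaluation.** Each rule gets a classifier label;
   compounds are featurized as MACCS structural keys plus per-rule trigger
   bits, and an ensemble of classifier chains (ECC) predicts which firing
   rules are trustworthy.  Evaluation sweeps a probability threshold and
   reports precision = TP/(TP+FP), recall = TP/(TP+FN) and the area under
   the PR curve — reaction by reaction (single-gen) or over whole pathways
   (multi-gen), where generation *g* products weigh w^(g−1) and
   unobserved intermediates that lead to correct products, as well as
   co-products of correct products, are not punished as false positives.
   A *genericity scan* repeats the pipeline at target levels
   {0, 1, 5, 10, 20, 50} and picks the level whose model assigns observed
   held-out reactions the highest mean probability.

Everything is exercised on bundled synthetic reaction families
(dechlorination, alcohol oxidation, ester hydrolysis, nitro reduction)
rather than external databases; see `docs/methods.md` for what the
generator does and does not emulate.

## Worked example

```python
from envirule import cluster, generate_ruleset, build_observed_index
from envirule.io import read_functional_groups
from envirule.synthetic import make_reaction_family

fgs = read_functional_groups()                       # bundled SMARTS library
rxns = make_reaction_family("alcohol_oxidation", n=4, seed=7)
rxns += make_reaction_family("dechlorination", n=3, seed=7)

groups = cluster(rxns, fgs)
print([(g.group_id, len(g.members), g.eligible) for g in groups])

observed = build_observed_index(rxns)
compounds = sorted({r.substrate_smiles for r in rxns})
rs = generate_ruleset(groups, 5.0, compounds, observed, fgs)
for rule in rs.rule_list:
    print(rule.group_id, rule.genericity, rule.smirks_list)
print(rs.rule_list[1].apply("CCCCCCCCCl"))
```

prints

```
[('group-0001', 4, True), ('group-0002', 3, True)]
group-0001 0.0 ['[O;+0:4]-[C;+0:7]>>[O+0:4]=[C+0:7]']
group-0002 0.0 ['[Cl;+0:3]-[C;+0:4]>>[C+0:4]']
frozenset({frozenset({'CCCCCCCC'})})
```

Two eligible groups were found (four secondary-alcohol oxidations, three
aliphatic dechlorinations).  Both tuned rules have genericity 0.0: on this
noise-free compound set every compound a rule fires on has observed
products, so NS = 0 and the tuner stays at the most generic state
(diameter 0 — the bare center).  The dechlorination rule applied to an
unseen octyl chloride yields one predicted product set, octane.

The same workflow is available from a shell:

```bash
envirule cluster --reactions rxns.txt --out groups.json
envirule generate --groups groups.json --target-genericity 5 --out rules.json
envirule add --ruleset rules.json --new-reactions new.txt --out rules2.json --report report.json
envirule apply --ruleset rules.json --compound "CCC(O)CC"
envirule eval single-gen --reactions rxns.txt --reps 100 --seed 1 --out report.csv
envirule scan-genericity --reactions rxns.txt --levels 0,1,5,10,20,50 --splits 5
```

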