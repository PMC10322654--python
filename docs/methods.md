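# Methods

This note documents the models and procedures implemented in `envirule`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic test corpora can
show.

## Reactions and atom–atom mapping

The unit of analysis is a single-substrate decomposition reaction: one
connected substrate, one or more products, and a bijection between their
heavy atoms expressed as SMILES atom-map numbers.  Pre-mapped reaction
SMILES are the first-class input; for small molecules an internal mapper
(`chem.map_atoms`) searches all element-respecting bijections for the one
minimizing the number of changed bonds (formed + cleaved + order-changed),
with ties broken by canonical atom rank so the result is independent of
input atom order.  The search is exhaustive and budget-limited
(`max_assignments`, default 2·10⁶ candidate assignments ≈ 10 heavy atoms
of mixed elements); larger reactions must arrive pre-mapped.  Hydrogens
are never mapped; hydrogen changes are inferred from heavy-atom valence.

Biotransformation databases omit small cosubstrates, so strict atom
balance is too strong a requirement.  A `CosubstrateConfig` exempts a
fixed element list from the bijection: product atoms with no substrate
counterpart (default: O, from water/O₂) are tagged *incoming*; substrate
atoms with no product image (default: O and the halogens, covering
reductive dehalogenation and nitro reduction) are tagged *leaving*.
Incoming atoms appear unmapped on the product side of emitted rules;
leaving atoms appear only on the substrate side.  How water-derived atoms
should enter fingerprints is not a settled convention; here incoming atoms
contribute their own center descriptors and their formed bonds, which
keeps e.g. hydrolyses distinct from eliminations.

## Reaction centers and fingerprints

The center of a reaction is the set of changed bonds (present on one side
only, or with a different order), their endpoint atoms, atoms whose total
hydrogen count or formal charge changed, and — when any of these atoms
intersects a match of a configured functional-group SMARTS — the entire
matched group.  A default library of 25 groups (esters, amides, nitro,
phosphate esters, halides, …) ships as editable YAML; the list is
configuration, not algorithm.

Fingerprints are three multisets of canonical descriptor strings: bond
formation/cleavage descriptors, bond-order-change descriptors, and one
descriptor per center atom.  Exact strings were chosen over hashed bit
vectors deliberately: clustering uses only the similarity-1.0 threshold,
and with multisets Tanimoto 1.0 is collision-free equality, making the
partition well defined, order-invariant and idempotent.

Center-atom descriptors are restricted to the center subgraph: element,
aromaticity, ring flag and charge of the atom; its bonds to other center
atoms before and after the reaction; and its hydrogen/charge deltas.
Neighbors outside the center are excluded on purpose — a primary and a
secondary alcohol oxidation share the same changed C–O bond and C–H loss
and must land in one group even though their carbinol carbons have
different neighbor counts.  The environment radius for cluster identity
is therefore effectively fixed and independent of the later, adjustable
rule diameter.

## Rule generation

For each group with ≥ 2 members, one composite rule is extracted; a
composite rule triggers when any of its simple rules triggers.

**Template shape.** The substrate side of a simple rule contains exactly
the center atoms (with element, aromaticity and charge, written with map
numbers); the product side rewrites their bonds, charges and any incoming
atoms.  Substituent context never becomes template atoms: the radius-*d*
environment of each center atom is attached as a recursive SMARTS
(`$(...)`) constraint on that atom, with atoms at exactly distance *d*
relaxed to element + aromaticity.  This has three consequences: the
product side never has to reproduce unchanged context; applying a rule
with RDKit keeps all unmatched atoms intact; and raising *d* (or the
explicit-H level) can only shrink the trigger set, which is the
monotonicity the tuner relies on.  Hydrogen counts after application are
recomputed from valence rather than written into the product template,
and product charges are applied in a post-processing step, which
side-steps toolkit-specific template semantics.

**Explicit hydrogens.** Level *h* adds total-H-count constraints to atoms
within *h* − 1 bonds of the center (center atoms first, then outward).
When environment constraints are present, each member's H count is
embedded in its own `$(...)` option rather than OR-ed at the position,
so an unobserved (environment, H-count) cross-combination can never
match.

**Combination.** Each member contributes, per center position, its
environment option.  Graphs merge only if every cross-position pairing of
options in the merged graph is observed in at least one member reaction;
a member with no substituent at a position is treated as unconstrained
there (substructure semantics cannot express absence — only explicit-H
constraints can pin a position closed).  For up to six graphs the
minimum-size legal partition is found by exhaustive enumeration
(Bell(6) = 203 partitions), because greedy pairwise merging was observed
to leave one rule too many on a four-reaction ester fixture; beyond six
a deterministic greedy (largest first, then lexicographic) is used.
Every emitted rule is verified to reproduce each of its source reactions
(as canonical product-SMILES sets); failure raises, it is never silently
dropped.

## Genericity and tuning

Genericity of a rule over a compound set is NS/PS: PS counts compounds on
which the rule fires and at least one predicted product set equals the
product set of an observed reaction of that compound; NS counts compounds
on which it fires with no such match.  PS = 0 with NS > 0 maps to +∞
("more generic than any target"); a rule that never fires is undefined
and treated as maximally specific.  The tuner evaluates the state path
(d = 0…d_sat, h = 0), then (d_sat, h = 1…d_sat+1), where d_sat is the
smallest diameter covering every member substrate (capped by
`max_diameter`, default 8), and returns the state whose genericity is
closest to the target, ties toward the more generic (earlier) state.
Full path enumeration is used instead of a literal walk; the state space
is linear and the returned state matches the "as close as possible"
criterion exactly.  Coverage of all group members is asserted at every
state.

## Incremental updates

The rule set persists every group's fingerprint, including singletons, so
a later reaction can make a stored singleton eligible.  New reactions
join the unique group with an identical fingerprint or found new groups;
only touched eligible groups are re-tuned, against the rule set's stored
target genericity.  This makes incremental addition equivalent to batch
re-clustering (asserted over randomized splits in the tests) while
leaving untouched rules byte-identical.

## Prediction models

Each composite rule is one label of a multi-label classifier.  Features
are the 166 public MACCS structural keys (bit 0 unused; 167-wide block)
concatenated with per-rule trigger bits; labels are positive/negative by
the PS/NS definition and missing where the rule does not fire — missing
labels are excluded from that label's loss, since the trigger bit already
encodes applicability.  The ensemble of classifier chains trains, per
chain, one L2-regularized logistic regression per label (C = 1,
deterministic seeds) in a chain-specific random label order; later labels
receive earlier labels' values as features (true labels during training,
thresholded predictions at inference), and probabilities are averaged
over chains (default 10, all seeded from one master seed).  A label
lacking either class falls back to a constant probability of 0.5 — an
uninformative prior, chosen over the class rate so that a one-class label
is never maximally confident.

## Evaluation

Thresholds sweep 101 evenly spaced values in [0, 1].  At each threshold,
the products of all rules with predicted probability ≥ t are compared
with observed products as canonical-SMILES sets.  Evaluation is per
*compound*: splits keep all reactions of a substrate together, and a test
compound with no documented reaction still contributes its predictions as
false positives — terminal pathway members and negative compounds are
real prediction targets, not skipped rows.  Precision at zero predictions
is defined as 1.0 (logged convention; avoids NaN in curve aggregation).
The reported AUC is the trapezoidal area under the recall-ordered
precision–recall curve with a (0, p_first) anchor — PR, not ROC.

Multi-generation evaluation expands predictions breadth first from the
pathway roots up to the reference pathway's maximum generation (an
explicit depth cap; a node limit of 2000 guards against combinatorial
blow-up).  A product at generation g carries weight w^(g−1); the weight
scheme is the simplest monotone discount and w is an exposed flag
(default 0.5), since the value is a modelling choice, not a derived
constant.  Two FP exemptions are applied, each switchable: unobserved
intermediates with a predicted descendant matching an observed node, and
unobserved co-products formed in the same reaction outcome as a matched
product.  With both exemptions off, weight 1 and depth-1 pathways, the
multi-generation report equals the single-generation report exactly
(tested identity).

The genericity scan regenerates rules at target levels {0, 1, 5, 10, 20,
50} (the default grid), trains a model per level on 80% of compounds, and
scores each held-out observed reaction by the predicted probability of
the rule that reproduces it (0 if no rule covers it); means ± sd over 5
splits are reported and the argmax level is selected.

## Synthetic study conditions

The generator builds reaction families from substituent pools around four
transform templates — aliphatic dechlorination, alcohol oxidation
(primary and secondary share one center), ester hydrolysis (with an
incoming water oxygen) and nitro reduction (with leaving oxygens) — plus
rooted pathway chains (dechlorination → oxidation → nitro reduction,
truncated to the requested depth, optional branching) and noise compounds
that fire rules without observed reactions.  All draws are seeded;
generation validates chemistry (parse, unique reaction site, sanitizable
products, one shared fingerprint per family) and fails loudly otherwise.

Default corpus sizes (12 reactions per family, ~50 compounds, 3 noise
compounds per family in the noisy variant, pathway sets of 6–8) were
chosen as the smallest sizes at which every code path — eligibility
filtering, combination, tuning, incremental updates, compound-level
splits — is exercised with stable statistics.

Two corpora are engineered with forced structure: a *genericity ladder*
(two dechlorinations plus 16 decoys arranged so diameters 0/1/2 give
NS/PS exactly 8.0/4.0/1.0, pinning the tuner's choice at target 5) and a
*scan corpus* (primary chlorides whose decoy strata make generic states
train against feature-inseparable negatives, the mid-specific state
against cleanly separable aromatic negatives, and very specific states
lose held-out coverage, so the scan's optimum is level 5 by
construction).

What the synthetic conditions do **not** emulate: multi-substrate
(condensation) chemistry, stereochemistry, tautomerism, aromaticity
perception edge cases, cosubstrates beyond water-oxygen and halide loss,
enzyme promiscuity gradients, and the label noise and imbalance of real
curated databases.  Perfect PR-AUC on the noise-free corpus therefore
demonstrates internal consistency of the pipeline, not expected
performance on real pathway data, where coverage and probability
calibration dominate.

## Known limitations

* The internal atom mapper is exhaustive and only suitable for small
  molecules; real corpora should be pre-mapped by a dedicated tool.
* Environment subtrees that close rings through other center atoms are
  truncated at the center boundary; the emitted constraint is weaker
  (never wrong, but less specific) for fused-ring centers.
* Substructure semantics cannot express the absence of a substituent;
  only explicit-H levels can close a position, so rules at h = 0 may stay
  more generic than the observed substrates suggest.
* Genericity along the specificity path is not guaranteed monotone (PS
  can shrink together with NS), which is why the tuner enumerates states
  instead of bisecting.
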