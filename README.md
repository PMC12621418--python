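# metapot

Simulation of the **metabolic potential** of soil microbiomes: what a
microbial community could synthesize under a given nutrient regime, which of
those capabilities track the physicochemical environment, and which organisms
are indispensable for them.

The package is aimed at microbial ecologists working with automatically
reconstructed, stoichiometry-free metabolic networks — one network per
metagenome (community-wide, *MetaG* scale) and one per metagenome-assembled
genome (genome-resolved, *MAG* scale) — where flux balance analysis is not an
option because curation and kinetic parameters are unavailable.

## The model

**Network expansion (scope).** A metabolic network is a set of Boolean
reactions r : *inputs* → *outputs*; reversible reactions act in both
directions. Given a *seed* set S of available nutrients, producibility is the
least fixpoint of

> a reaction fires as soon as all of its inputs are available; its outputs
> then become available,

starting from S. The *scope* σ(N, S) is the set of compounds synthesized by
fired reactions (seeds are excluded unless regenerated; a flag includes
them). Scope is monotone in both S and the reaction set, deterministic, and
order-independent. Stoichiometry, flux, and costs are deliberately ignored —
the result is an upper bound on what the system could make.

**Community (mixed-bag) scope.** For a consortium {N₁…Nₖ} the community scope
is σ(∪ᵢNᵢ, S): all reactions are pooled as if cell walls were no barrier. The
*cooperation potential* σ(∪ᵢNᵢ, S) \ ∪ᵢσ(Nᵢ, S) is what only cross-feeding
can explain.

**Producibility matrix and metabolite groups.** Simulating every system
(site × scale) under every seed condition gives a binary metabolites ×
simulations matrix (the canonical design: 6 sites × 2 scales × 5 conditions =
60 columns). Metabolites producible at MAG scale but never at MetaG scale are
removed as gap-filling artifacts of genome-resolved reconstruction. Rows with
identical producibility vectors collapse into *metabolite groups*.

**Environment association.** Each of 17 physicochemical variables (pH, EC,
organic matter, element concentrations) is regressed on the group matrix with
an elastic net (glmnet-style mixing α = 0.85), penalty chosen by
leave-one-site-out cross-validation with the one-standard-error rule. Groups
with a standardized |coefficient| > 0.3 for any variable are *selected*; their
members are the *key metabolites*. Variables are clustered by |coefficient|
profile (Bray–Curtis dissimilarity, Ward-type linkage).

**Minimal communities.** For each site's MAG collection, the smallest member
subsets whose mixed-bag scope covers the key metabolites are enumerated
exactly. Members of every solution are *essential* syntrophic organisms,
members of some solutions are *alternative* (interchangeable) ones, and
MC:KS = 100·k/|key species| summarizes rigidity — 100 % means a unique,
irreplaceable consortium.

The five canonical seed conditions (basal medium ⊂ each of simple sugars,
complex sugars, non-sulfured amino acids, all amino acids; sizes
43/50/64/61/63) ship with the package; user-defined conditions extend any
parent by union.

## Worked example

Generate a synthetic six-site world (abstract metabolite ids, planted
cross-feeding, redundancy, artifacts, and environment associations with a
ground-truth manifest) and run the full pipeline:

```bash
metapot simulate --seed 42 --out world42
metapot run-all --world world42 --out run42 --seed 42
```

`run42/report.json` then contains, among per-stage summaries (numbers from
this exact invocation):

* `grid`: 60 cells — 6 sites × 2 scales × 5 conditions, each cell one scope;
* `filter`: 5 metabolites removed (exactly the world's planted MAG-only
  artifacts), 224 kept;
* `collapse`: 18 metabolite groups; 27 core metabolites per scale
  (producible in all 30 site × condition combinations of that scale);
* `associate`: 60 observations, 4 selected groups, 12 key metabolites —
  the world planted 4 associated groups;
* `mincom` (e.g. site S2): k = 1, one solution, MC:KS = 100 % — a single MAG
  suffices for the key metabolites that are producible at MAG scale there.

Individual stages are also available as `metapot scope | grid | collapse |
associate | mincom` on files (SBML or a tabular dialect for networks, plain
text for seed and target lists, TSV for matrices and environment tables):

```bash
$ metapot scope --network chain.tsv --seeds seeds.txt
B
C
# scope size: 2
```

## Layout

```
src/metapot/
  network_model.py        networks, SBML/tabular I/O, expansion engine
  conditions.py           seed conditions and the canonical library
  community_scope.py      individual/community scopes, cooperation potential
  producibility_matrix.py grid, gap-fill filter, groups, core metabolites
  env_association.py      elastic net, key metabolites, variable clustering
  minimal_communities.py  exact minimal-community enumeration & classification
  synthetic_data.py       synthetic worlds with ground-truth manifests
  pipeline.py, cli.py     orchestration and the `metapot` command
docs/methods.md           model assumptions, parameters, design choices
```
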