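# Methods

## Producibility model

The unit of modeling is a stoichiometry-free metabolic network: reactions are
(reactant-set, product-set, reversible) triples over string metabolite ids,
with coefficients discarded at parse time. Producibility is Boolean network
expansion: a directed rule fires when all its inputs are available, outputs
become available, and the scope is the least fixpoint reached from the seed
nutrients. The engine is a counting propagation (each rule tracks how many
inputs it still misses) and runs in time linear in total rule input size, so
brute-force oracles and exhaustive community searches stay cheap in tests.

Assumptions worth stating explicitly:

* **Cost-free Boolean semantics.** Reactions, enzyme expression, and
  transport are free; concentrations do not exist. Scopes therefore
  overestimate in-situ capability and are best read as the upper bound of a
  community's metabolic response.
* **Reversibility as two independent rules.** Each reversible reaction
  contributes a forward and a swapped rule. How reconstruction-tool
  reversibility annotations should be treated in expansion is genuinely open;
  splitting is the standard treatment and is applied uniformly.
* **Seed-exclusive scopes.** The reported scope contains only synthesized
  compounds; a seed appears in it only if some fired rule regenerates it.
  The inclusive variant (scope ∪ seeds) is available via ``include_seeds``
  everywhere, and the matrix records which convention produced it. Counts in
  reports therefore reflect synthesized compounds only.
* **Exact string identity.** Metabolite ids are compared literally; no
  cross-database reconciliation is attempted. SBML round-trips escape
  database-style characters (`MG+2`, `CL-`) reversibly.
* **Reactions with an empty side are rejected**, not treated as exchange or
  always-firing rules — an empty reactant set would silently inject seeds.

## Seed conditions

The canonical library holds five nested conditions (basal medium 43 seeds;
simple sugars +7; complex sugars +21; non-sulfured amino acids +18; all amino
acids +20, the last two differing by exactly cysteine and methionine). The
packaged file names every compound whose identity is public knowledge
(MetaCyc-style frame ids) and fills the remainder with flagged
`*-UNSPEC-*` placeholder ids so that sizes and nesting are exact on synthetic
universes; every placeholder is listed in the file's `placeholders` sections.
Conditions are network-independent: seed ids missing from a network are
inert by design, so one library serves any universe.

## Community semantics

Community scope pools all members' reactions ("mixed-bag"/superorganism
semantics) with no transporter gating; duplicate rules collapse by content.
This is an upper bound on cross-feeding. The cooperation potential (community
scope minus the union of individual scopes) is only defined for
genome-resolved systems; for single-member systems it is empty by
construction and requesting it is an error rather than a silent zero.

## Matrix, filter, groups

The simulation grid takes the cartesian product of systems and conditions;
missing cells abort the build (zeros are biologically meaningful, so nothing
is imputed). The gap-fill artifact filter removes metabolites with at least
one 1 among genome-resolved columns and all 0 among metagenome columns; it is
idempotent and a no-op (with a warning) when only one scale is present.
Groups are maximal sets of identical rows, named `g0001…` after sorting by
(vector as bit-string, first member id) so ids are stable across row order.

## Environment association

Design: one observation per simulation column; the predictor is the group's
producibility in that column, the response the site's standardized
measurement replicated over that site's columns. The replication is the
reason cross-validation is grouped by site (leave-one-site-out) — ungrouped
folds would leak the held-out site's response into training. A site-level
aggregated design (mean producibility per site) is available by
configuration; what the regression's observational unit "should" be is not
determined by the study design itself, and every report records the unit
used.

Fitting: elastic net with mixing 0.85 between lasso and ridge, predictors and
response standardized (population sd) so coefficients live on one scale and a
single threshold (default 0.3, strict inequality) is meaningful across
variables in incommensurable units. Penalty strength comes from the grouped
CV curve under the **one-standard-error rule** — the largest penalty whose
mean CV error is within one SE of the minimum, the convention glmnet reports
by default. With only six sites, the minimal-error penalty admits decoy
predictors whose chance correlation with a noise response is large
(measured on synthetic worlds: ≈4.7 spurious selections per world at
threshold 0.3, versus ≈0.3 under the 1-SE rule at planted-association
sensitivity 0.93); the parsimony rule is therefore the default, and
``penalty_rule="min"`` remains available. Zero-variance predictors (e.g. the
core-metabolite group, which is 1 everywhere) are flagged and excluded with
coefficient 0. Coefficient magnitudes are descriptive; no significance
testing or multiplicity control is applied or implied.

Variable clustering uses Bray–Curtis dissimilarity between |coefficient|
profiles and Ward-type agglomeration on the precomputed dissimilarities (the
ward.D2-style usage); the flat cut defaults to three clusters and is
configurable.

## Minimal communities

Targets are first partitioned by full-community producibility; unproducible
targets are excluded from solving and reported. The solver is self-contained
and exact: members that cannot fire any rule even with every full-community
product available are pruned (they cannot help any subset); members whose
removal from the full community breaks coverage are *forced* into every
solution, and iterative deepening then searches combinations of the remaining
members in lexicographic order. Enumeration returns every minimum-size cover
(default cap 10 000 solutions; beyond the cap the result is flagged and the
essential/alternative classification is suppressed rather than computed from
a truncated set). Substitutable groups are the connected components of the
pairwise swap relation (replacing one member by the other maps every
containing solution to a valid solution); essential members are excluded by
construction. Ties everywhere are broken by sorted member ids, so output is
deterministic.

## Synthetic worlds

The generator emulates the study design the pipeline assumes: six sites, each
with 8–20 organism networks whose reaction union plus extra "unbinned"
pathways forms the site's metagenome network. Structure is planted per site
and recorded in a manifest:

* linear pathways (length 2–6) rooted in basal seeds, with optional basal
  co-substrates and reversible interior steps (first and co-substrate steps
  stay irreversible so reverse rules never synthesize seed compounds);
* a fraction of pathways split across two organisms at a random cut —
  the post-cut products are the planted cooperation-only metabolites;
* per site, three targets carried by dedicated single organisms (planted
  essential members) and two targets carried redundantly by two dedicated
  organisms each (planted interchangeable classes), giving k = 5,
  2² = 4 solutions, and MC:KS = 5/7 ≈ 71.4 % under defaults;
* five artifact metabolites producible in one organism but absent from every
  metagenome network (what genome-resolved gap-filling looks like);
* four planted group↔variable associations: a pathway present in a balanced
  half of the sites, and an environmental variable equal to ±0.6 × the
  standardized presence pattern plus N(0, 0.2) noise. Patterns are distinct
  and pairwise non-complementary — a complementary pair is perfectly
  anti-correlated over sites, which would make the two planted claims
  unidentifiable by any estimator. Remaining variables are standard normal.
* a quarter of non-target pathways root in a non-basal condition's additions,
  so some groups are condition-sensitive rather than purely site-driven.

Expected scopes in the manifest are derived *constructively* from pathway
bookkeeping (a pathway's metabolites are producible wherever the pathway is
present and its root is among the condition's seeds), not by running the
expansion engine — the manifest is therefore a legitimate oracle for it.

What the worlds do **not** emulate: real biochemistry (ids are abstract),
branched/cyclic topologies beyond co-substrates, abundance–producibility
coupling, correlated environmental variables, annotation noise, and
incomplete binning beyond the unbinned-pathway device. Passing recovery tests
on these worlds shows the machinery is correct and calibrated for the planted
effect sizes; it does not certify recovery rates on real soils, where
identifiability with six sites is the binding constraint.

## Problem sizes and numerics

Default worlds use a 300-id universe, seven per-site pathways plus six shared
and one unbinned per site; a full 60-cell grid with association and
minimal-community stages completes in about a second, and the repository's
acceptance measurements (50 oracle networks up to 200 reactions, 50 exact
enumeration instances up to 12 members, 20-world association replicates) run
in well under a minute — sizes chosen so exhaustive oracles remain feasible
alongside the method. Elastic-net fits cap coordinate descent at 5×10⁴
iterations on a 100-point penalty path; convergence warnings on tiny folds
are suppressed as benign. All randomness flows from explicit integer seeds;
world regeneration and pipeline reruns are byte-identical, and the pipeline
config hash covers input file content rather than paths.

## Known limitations

* Mixed-bag pooling cannot distinguish cross-feeding from co-occurrence of
  partial pathways; it is an upper bound by design.
* With six sites, elastic-net selection operates at the edge of
  identifiability; the 0.3 threshold on standardized coefficients is a
  descriptive cutoff, not an error-controlled test.
* The minimal-community search is exponential in the worst case; the forced-
  member reduction makes planted-structure instances easy, but adversarial
  instances with many interchangeable members can still be expensive (the
  solution cap guards enumeration, not the minimum-size search).
* Scope semantics treat every metabolite of a community as available to all
  members; transporter annotation is out of scope.
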