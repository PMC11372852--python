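# Methods

## The bias being studied

A discrete estimator is biased when its most probable value is not the
truth.  For an unrooted quartet generated from a star tree (internal branch
t₀ = 0) with tip lengths t₁ … t₄, every resolved topology is wrong, so an
unbiased ML estimator should return T1, T2, T3 with probability 1/3 each
(or report the star).  Short branch attraction (SBA) is the systematic
departure from this: the topology grouping the two shortest-branch taxa is
returned far more often.  The package quantifies the effect twice over —
exactly, through site-pattern theory, and empirically, through simulation
with its own ML engine — and implements the polytomy-collapse remedy.

## Exact pattern theory (JC69)

Under JC69 all members of an equality-structure class are equiprobable, so
the 15 class probabilities are computed by exhaustive enumeration: for a
star quartet, sum the product of four transition probabilities over the 4
root states and 256 leaf tuples; for a bifurcating quartet (fixed as
T2 = S1S3|S2S4, with S1, S3 on one internal node), mix the
matched-internal-state star term (weight 1/4 + 3/4·e^(−4t₀/3)) with the
mismatched term (second state uniform over the three others).  Enumeration
is preferred over transcribed closed-form expressions because it is
unambiguous and self-checking: the test suite verifies Σp = 1, the
equality of the mixture with a direct 16-state × 256-tuple sum, and the
t₀ → 0 degeneration to the star probabilities (1e-12).

Two inequalities characterize SBA and are verified numerically over random
branch-length draws rather than symbolically: (i) the four singleton
classes together always outweigh the three informative classes — so a
single site is more likely to leave the quartet unresolved than to resolve
it; (ii) whenever max(t₁,t₂) < min(t₃,t₄), the informative class pairing
the two short branches strictly dominates the other two.

The exact finite-length distribution of the count-argmax topology sums the
4-category multinomial pmf (three informative classes plus a pooled rest)
over all compositions of K, in log space.  The enumeration is capped at
K = 200 (O(K³) compositions stay sub-second); beyond that the package
points to Monte Carlo, and the test suite checks the enumeration against a
200,000-replicate simulation of the same argmax rule.  Ties are assigned to
the star outcome or split equally among the tied topologies ("random"),
the expected behaviour of a program forced to bifurcate.

## Substitution models and simulation

GTR+Γ uses the reversible rate matrix built from π and six
exchangeabilities, normalized to one expected substitution per site per
unit branch length, with 4 equal-probability discrete-gamma categories
(mean-of-bin rates, mean exactly 1).  Transition matrices come from the
symmetrized eigendecomposition; a stationarity test (πP(t) = π to 1e-10)
guards the algebra.  The per-replicate random-model scheme draws
π ~ Dirichlet(1,1,1,1) (floored at 1e-6), exchangeabilities i.i.d.
LogNormal(0, 1) normalized by the G–T rate (any positive-spread law
reproduces the qualitative results; this normalization is the common GTR
convention), and α ~ Normal(0.5, sd 0.1) truncated positive.

The sequence simulator draws the root state from π and evolves sites down
the tree with an independently resampled rate category per site (the
Seq-Gen default semantics).  Gaps use symbol "-"; gap-containing columns
are excluded from pattern classification and enter likelihoods through a
marginalized (all-ones) leaf state.

## Multispecies coalescent

Species trees carry branch lengths τ and population sizes θ, both in
mutation units, with pairwise coalescence rate 2/θ (k lineages coalesce at
rate k(k−1)/θ) — the MP-EST/phybase convention.  Species trees need not be
ultrametric: each population is simulated for its own duration, lineages
synchronize at speciation nodes, and a tip branch contributes its printed τ
to the terminal gene-tree branch.  The closed forms exp(−2τ/θ) (two
lineages fail to coalesce), exp(−6τ/θ) (three lineages), and their product
for root-population coalescence are validated against the simulator's own
per-population event counts, not against external tables.  The three study
species trees use root θ = 1e-4 and θ = 0.01 on other ancestral branches.

## The ML engine and its tie handling — the crux

The engine computes the pruning likelihood over unique site patterns with
gamma categories averaged, and optimizes one branch at a time by bounded
scalar search in log-length space on [1e-10, 10], cycling until the
per-sweep gain falls below 1e-8 (cached outside-subtree partials make each
one-dimensional evaluation two tensor contractions).  The lower bound is
deliberately 1e-10 rather than a conventional 1e-6 so that estimated
internal branches can fall below the 1e-5 polytomy threshold used by the
remedy.  Quartets are solved exhaustively (all three topologies); larger
trees by NJ (JC distances) + NNI hill-climbing with candidate
rearrangements pre-scored by a one-sweep local optimization of the five
surrounding branches and accepted only after full re-optimization improves
the likelihood.  Taxon order is canonicalized, so row permutations cannot
change the result.

A central analytical fact shapes the engine design: whenever the two
short-branch taxa have *identical* sequences, the maximized likelihoods of
all three quartet topologies tie **exactly** (each reduces, at its optimum,
to the same three-taxon star profile; verified by direct computation).  At
the study's branch lengths this is the dominant data configuration, so the
attraction observed with shell programs is not a property of the
likelihood surface but of how those programs resolve flat surfaces — in
particular their duplicate-sequence reduction, which re-attaches identical
sequences as cherries of the retained copy.  The package therefore exposes
two modes:

* `ml_quartet` / `ml_search` — the fair engine: exhaustive scoring, ties
  detected at 1e-9 log-units and resolved by a seeded uniform draw (or an
  explicit star).  On identical or saturated sequences its topology
  frequencies are uniform; this is asserted by the fairness tests.
* `ml_tree` — the program-faithful pipeline used by the scenario runners:
  duplicate sequences are removed before inference and re-inserted next to
  their representative afterwards (each insertion subdivides the
  representative's terminal branch, so the last-listed duplicate sits
  closest), then all branch lengths are re-optimized.  This single,
  documented mechanism reproduces the attraction: the wrong tree is
  returned with its internal branch at the optimizer's lower bound, i.e.
  far below 1e-5 — which is precisely why the collapse remedy works.

## NJst and the remedy

NJst averages, over gene trees, the number of internal nodes on the path
between each species pair (a polytomy vertex counts once) and applies
neighbor joining (scikit-bio's implementation; negative branch estimates
clamped to zero).  Because the distance is topological, collapsing an
estimated internal branch < 1e-5 into a polytomy removes exactly one node
from every path through it — so the remedy weakens artifactual splits
without touching genuine ones.  `collapse_short_branches` contracts
internal edges below the threshold (leaf edges never), and the
species-tree runner reports, per sequence length, the number of
wrong-topology gene trees, how many of them have internal branch < 1e-5,
and the residual resolved-wrong count after collapsing — a paired
comparison on the same fitted trees.

## Scenario runners and problem sizes

Every scenario is a pure function of (config, master seed); records carry
per-replicate outcomes, and proportions are reported with binomial
standard errors sqrt(p(1−p)/n).  Non-informative scenarios (identical,
saturated, saturated+missing, equal-branch star) use the fair engine with
random ties and test the topology counts against (1/3, 1/3, 1/3) with an
exact multinomial test (tail of outcome probabilities ≤ the observed one;
χ² above n = 500).  Identical/saturated inputs have no generating tree
model, so they are analyzed under JC; the equal-branch star scenario is
analyzed under its own sampled GTR+Γ model.  Scenario inference generally
fixes the generating model's parameters rather than re-estimating them:
topology bias under SBA is model-robust, and full GTR estimation would add
engineering without changing the decision surface.

Default study sizes are 100 replicates per length for gene-tree scenarios
and 1,000 gene trees for species-tree scenarios.  The shipped test suite
and acceptance script scale some of these down — 50–120 replicates for the
8-taxon and pipeline tests, 300 gene trees for the star pipeline and 200
for the 8-taxon pipeline — and always compare at 3 binomial standard
errors for the size actually run.

## What the synthetic data do and do not show

The generators emulate the study conditions exactly: fixed scenario trees
with the printed branch lengths, per-replicate random GTR+Γ models, and
coalescent gene trees with the printed θ values.  They do not emulate
indels, selection, rate heterogeneity across loci beyond the sampled α, or
alignment error, so passing tests demonstrate the mechanics of SBA and its
remedy under the model, not the prevalence of SBA in any particular
empirical data set.

## Known limitations

* The attraction proportions at very short alignments (K = 100) depend on
  which taxa happen to join the identical-sequence cluster; with three or
  more mutually identical sequences no data-driven rule can prefer one
  pairing, so the scenario proportions there sit below what programs with
  additional order-dependent behaviour may report.
* NNI-only search (no SPR/TBR) — adequate for 8 taxa, not for large trees.
* No model-parameter estimation from data; inference uses the generating
  model (or JC), which is a deliberate simplification.
* The exact ML-topology distribution is the distribution of the
  informative-count argmax, the K-site analogue of the single-site
  argument; it coincides with full ML under JC for star data in the
  regimes studied but is not a general ML theorem.
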