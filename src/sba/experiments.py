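"""End-to-end scenario runners for the short-branch-attraction study.

Three families of simulation are covered, each fully determined by a
(config, master seed) pair:

* non-informative inputs (identical, saturated, star-with-equal-branches
  alignments) probing whether the ML engine is fair — a fair engine
  returns the three quartet topologies uniformly, tested against
  (1/3, 1/3, 1/3) with the exact multinomial test;
* gene-tree scenarios: alignments simulated from fixed 4- and 8-taxon
  trees under per-replicate random GTR+Gamma models, ML topologies
  re-estimated, and the frequency of the short-branch-attraction grouping
  recorded;
* species-tree scenarios: gene trees simulated under the multispecies
  coalescent, per-gene alignments and ML gene trees, NJst species-tree
  estimation, and the polytomy-collapse remedy diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from sba.models import JCModel, sample_gtr_params
from sba.msc import SpeciesTree, simulate_gene_tree, species_tree_8taxon, species_tree_bif, species_tree_star
from sba.ml_infer import ml_quartet, ml_tree
from sba.njst import njst
from sba.seqsim import (
    apply_missing,
    make_identical_alignment,
    make_saturated_alignment,
    simulate_alignment,
)
from sba.trees import (
    BIF3,
    BIF4,
    STAR1,
    STAR2,
    TREE8,
    QuartetTopology,
    Tree,
    is_monophyletic,
    parse_newick,
    quartet_topology,
    write_newick,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "GENE_TREE_SCENARIOS",
    "run_gene_tree_scenario",
    "run_species_tree_scenario",
    "run_noninformative_scenario",
    "multinomial_gof",
    "proportion_se",
]

GENE_TREE_SCENARIOS = {
    "star1": STAR1,
    "star2": STAR2,
    "bif3": BIF3,
    "bif4": BIF4,
    "tree8": TREE8,
}

SPECIES_TREE_SCENARIOS = {
    "sp-star": species_tree_star,
    "sp-bif": species_tree_bif,
    "sp-8": species_tree_8taxon,
}

NONINFORMATIVE_SCENARIOS = ("identical", "saturated", "saturated_missing", "star_equal")

SATURATED_FREQS = (0.1, 0.2, 0.3, 0.4)
STAR_EQUAL = "(S1:0.01,S2:0.01,S3:0.01,S4:0.01);"
COLLAPSE_EPS = 1e-5


@dataclass
class ScenarioConfig:
    """Settings of one scenario run.

    ``n_reps`` is the replicate count for gene-tree and non-informative
    scenarios; ``n_genes`` the gene-tree count for species-tree scenarios.
    ``collapse`` switches on the polytomy remedy at the given threshold
    for the species-tree pipeline.
    """

    name: str
    lengths: tuple[int, ...] = (100, 500, 1000)
    n_reps: int = 100
    n_genes: int = 1000
    seed: int = 0
    tie_rule: str = "random"
    collapse: float | None = None
    tree_newick: str | None = None

    def __post_init__(self):
        if self.n_reps < 1 or self.n_genes < 1:
            raise ValueError("replicate counts must be >= 1")
        if any(k < 1 for k in self.lengths):
            raise ValueError("sequence lengths must be positive")


@dataclass
class ScenarioResult:
    """Aggregated scenario output.

    ``proportions`` has one row per (length, category) with count, n,
    proportion, binomial standard error and (where computed) the exact
    multinomial goodness-of-fit p-value against (1/3, 1/3, 1/3);
    ``records`` holds one dict per replicate (seed-reproducible);
    ``extras`` carries scenario-level artifacts such as estimated species
    trees.
    """

    config: ScenarioConfig
    proportions: pd.DataFrame
    records: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def proportion(self, length: int, category: str) -> float:
        df = self.proportions
        row = df[(df["length"] == length) & (df["category"] == category)]
        if row.empty:
            return 0.0
        return float(row["proportion"].iloc[0])


def proportion_se(p: float, n: int) -> float:
    """Binomial standard error sqrt(p (1 - p) / n)."""
    return math.sqrt(max(p * (1.0 - p), 0.0) / n)


# ---------------------------------------------------------------------------
# Multinomial goodness of fit


def multinomial_gof(counts, expected) -> float:
    """Exact multinomial goodness-of-fit p-value for 3 categories.

    The p-value is the total probability of outcomes whose probability
    under ``expected`` does not exceed that of the observed outcome
    (exact for n <= 500; Pearson chi-square approximation above).
    """
    counts = np.asarray(counts, dtype=np.int64)
    expected = np.asarray(expected, dtype=float)
    if counts.shape != (3,) or np.any(counts < 0):
        raise ValueError("need 3 non-negative counts")
    if not np.isclose(expected.sum(), 1.0):
        raise ValueError("expected probabilities must sum to 1")
    n = int(counts.sum())
    if n == 0:
        raise ValueError("zero total count")
    if n > 500:
        exp_counts = n * expected
        stat = float(((counts - exp_counts) ** 2 / exp_counts).sum())
        return float(chi2.sf(stat, df=2))
    grid = np.arange(n + 1)
    a, b = np.meshgrid(grid, grid, indexing="ij")
    a, b = a.ravel(), b.ravel()
    keep = a + b <= n
    a, b = a[keep], b[keep]
    c = n - a - b

    def xlogp(k, p):
        if p > 0:
            return k * math.log(p)
        return np.where(k == 0, 0.0, -np.inf)

    logpmf = (
        gammaln(n + 1)
        - gammaln(a + 1)
        - gammaln(b + 1)
        - gammaln(c + 1)
        + xlogp(a, expected[0])
        + xlogp(b, expected[1])
        + xlogp(c, expected[2])
    )
    pmf = np.exp(logpmf)
    obs = (a == counts[0]) & (b == counts[1])
    p_obs = float(pmf[obs][0])
    return float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# Aggregation helpers

QUARTET_ORDER = ["S1", "S2", "S3", "S4"]
_TOPO_CATEGORIES = [t.value for t in QuartetTopology]


def _aggregate(records: list[dict], categories: list[str], with_test: bool = False) -> pd.DataFrame:
    rows = []
    lengths = sorted({r["length"] for r in records})
    for K in lengths:
        sub = [r for r in records if r["length"] == K]
        n = len(sub)
        counts = {c: sum(1 for r in sub if r["category"] == c) for c in categories}
        p_value = None
        if with_test:
            resolved = [counts.get(t.value, 0) for t in (QuartetTopology.T1, QuartetTopology.T2, QuartetTopology.T3)]
            if sum(resolved) > 0:
                p_value = multinomial_gof(resolved, (1 / 3, 1 / 3, 1 / 3))
        for c in categories:
            p = counts[c] / n
            rows.append(
                {
                    "length": K,
                    "category": c,
                    "count": counts[c],
                    "n": n,
                    "proportion": p,
                    "se": proportion_se(p, n),
                    "p_value": p_value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario runners


def run_gene_tree_scenario(config: ScenarioConfig, rng: np.random.Generator | None = None) -> ScenarioResult:
    """Simulate alignments from a fixed gene tree under per-replicate
    GTR+Gamma models and re-estimate ML trees.

    Inference uses the program-faithful pipeline (:func:`sba.ml_infer.ml_tree`,
    duplicate-sequence reduction included), the analogue of running a shell
    ML program on each replicate.  For 4-taxon scenarios the recorded
    category is the quartet topology in leaf order (S1, S2, S3, S4) — the
    short-branch artifact is T2 = S1S3|S2S4 for the star/bifurcating
    scenario trees.  For the 8-taxon scenario the category is whether
    {A, B} forms a bipartition side.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    newick = config.tree_newick or GENE_TREE_SCENARIOS[config.name]
    tree = parse_newick(newick)
    n_leaves = len(tree.leaf_labels())
    records: list[dict] = []
    for K in config.lengths:
        for rep in range(config.n_reps):
            model = sample_gtr_params(rng)
            aln = simulate_alignment(tree, model, K, rng)
            if n_leaves == 4:
                fit = ml_tree(aln, model, tie_rule=config.tie_rule, rng=rng)
                records.append(
                    {
                        "length": K,
                        "rep": rep,
                        "category": fit.topology.value,
                        "internal_length": fit.internal_length,
                    }
                )
            else:
                fit = ml_tree(aln, model, rng=rng)
                grouped = is_monophyletic(fit.tree, {"A", "B"})
                records.append(
                    {
                        "length": K,
                        "rep": rep,
                        "category": "AB" if grouped else "other",
                    }
                )
    categories = _TOPO_CATEGORIES if n_leaves == 4 else ["AB", "other"]
    return ScenarioResult(config, _aggregate(records, categories), records)


def run_noninformative_scenario(config: ScenarioConfig, rng: np.random.Generator | None = None) -> ScenarioResult:
    """Estimate ML quartets from deliberately signal-free inputs and test
    the topology frequencies against the uniform (1/3, 1/3, 1/3) law.

    Identical and saturated sequences are analyzed under JC (no generating
    tree model exists); the equal-branch star scenario samples a GTR+Gamma
    model per replicate and uses it for inference.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.name not in NONINFORMATIVE_SCENARIOS:
        raise ValueError(f"unknown scenario {config.name!r}")
    star_equal = parse_newick(STAR_EQUAL)
    records: list[dict] = []
    for K in config.lengths:
        for rep in range(config.n_reps):
            if config.name == "identical":
                aln, model = make_identical_alignment(K, rng), JCModel()
            elif config.name == "saturated":
                aln, model = make_saturated_alignment(K, SATURATED_FREQS, rng), JCModel()
            elif config.name == "saturated_missing":
                aln = apply_missing(
                    make_saturated_alignment(K, SATURATED_FREQS, rng), 0.1, ["S1", "S2"], rng
                )
                model = JCModel()
            else:
                model = sample_gtr_params(rng)
                aln = simulate_alignment(star_equal, model, K, rng)
            fit = ml_quartet(aln, model, tie_rule=config.tie_rule, rng=rng)
            records.append({"length": K, "rep": rep, "category": fit.topology.value})
    return ScenarioResult(config, _aggregate(records, _TOPO_CATEGORIES, with_test=True), records)


def run_species_tree_scenario(config: ScenarioConfig, rng: np.random.Generator | None = None) -> ScenarioResult:
    """Full species-tree pipeline: MSC gene trees, per-gene alignments and
    ML gene trees, NJst estimation, and remedy diagnostics.

    Per sequence length the result records, for every gene, the true
    gene-tree quartet topology (or {A,B} grouping), the estimated one, and
    the estimated internal branch length (4-taxon case).  Extras hold, per
    length: the NJst species tree from the estimated gene trees (with the
    collapse remedy if configured), the NJst species tree from the true
    gene trees, and the fraction of wrong-topology ML gene trees whose
    internal branch is below 1e-5.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stree = SPECIES_TREE_SCENARIOS[config.name]()
    n_leaves = len(stree.tree.leaf_labels())
    records: list[dict] = []
    extras: dict = {"per_length": {}}
    for K in config.lengths:
        fitted_trees: list[Tree] = []
        true_trees: list[Tree] = []
        for gene in range(config.n_genes):
            gtree = simulate_gene_tree(stree, rng)
            model = sample_gtr_params(rng)
            aln = simulate_alignment(gtree, model, K, rng)
            true_trees.append(gtree)
            if n_leaves == 4:
                aln = aln.take(QUARTET_ORDER)
                true_topo = quartet_topology(gtree, QUARTET_ORDER)
                fit = ml_tree(aln, model, tie_rule=config.tie_rule, rng=rng)
                records.append(
                    {
                        "length": K,
                        "rep": gene,
                        "category": fit.topology.value,
                        "true_topology": true_topo.value,
                        "internal_length": fit.internal_length,
                        "wrong": fit.topology != true_topo,
                    }
                )
            else:
                fit = ml_tree(aln, model, rng=rng)
                grouped = is_monophyletic(fit.tree, {"A", "B"})
                true_grouped = is_monophyletic(gtree, {"A", "B"})
                records.append(
                    {
                        "length": K,
                        "rep": gene,
                        "category": "AB" if grouped else "other",
                        "true_category": "AB" if true_grouped else "other",
                    }
                )
            fitted_trees.append(fit.tree)
        per_length = {
            "species_tree": write_newick(njst(fitted_trees, collapse=config.collapse)),
            "species_tree_from_true": write_newick(njst(true_trees)),
        }
        if n_leaves == 4:
            sub = [r for r in records if r["length"] == K]
            wrong = [r for r in sub if r["wrong"]]
            n_wrong = len(wrong)
            n_wrong_short = sum(1 for r in wrong if r["internal_length"] < COLLAPSE_EPS)
            per_length.update(
                {
                    "n_wrong": n_wrong,
                    "n_wrong_short": n_wrong_short,
                    "wrong_short_fraction": (n_wrong_short / n_wrong) if n_wrong else float("nan"),
                    "resolved_wrong_after_collapse": n_wrong - n_wrong_short,
                }
            )
        extras["per_length"][K] = per_length
    categories = _TOPO_CATEGORIES if n_leaves == 4 else ["AB", "other"]
    return ScenarioResult(config, _aggregate(records, categories), records, extras)
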