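"""Species-tree estimation misled by biased gene trees, and the remedy.

Runs the star-species-tree pipeline end to end: coalescent gene trees, a
1,000-bp alignment per gene, ML gene-tree estimation, NJst species-tree
estimation, and the polytomy-collapse diagnostics.
"""

from sba.experiments import ScenarioConfig, run_species_tree_scenario

config = ScenarioConfig(name="sp-star", lengths=(1000,), n_genes=100, seed=11)
result = run_species_tree_scenario(config)
stats = result.extras["per_length"][1000]

print("Star species tree (S1:0.0001, S2:0.01, S3:0.0001, S4:0.01), theta0=1e-4")
print(f"P(ML gene tree groups S1,S3) = {result.proportion(1000, 'T2'):.2f}  "
      "(true gene trees: 1/3 each)")
print("NJst species tree from ML gene trees: ", stats["species_tree"])
print("NJst species tree from true gene trees:", stats["species_tree_from_true"])
print(f"wrong-topology ML gene trees: {stats['n_wrong']}, of which "
      f"{stats['n_wrong_short']} have internal branch < 1e-5 "
      f"({100 * stats['wrong_short_fraction']:.0f}%)")
print(f"resolved wrong quartets after collapsing at 1e-5: "
      f"{stats['resolved_wrong_after_collapse']} (was {stats['n_wrong']})")

print(
    "\nThe biased ML gene trees consistently group the two short-branch species,\n"
    "so NJst returns that wrong species tree; almost all of the wrong gene trees\n"
    "carry an internal branch below 1e-5, so collapsing them to polytomies\n"
    "removes most of the artifactual resolution before species-tree estimation."
)
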