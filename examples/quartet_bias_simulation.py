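"""Short branch attraction in simulated gene trees.

Simulates alignments from the two 4-taxon star scenario trees under
per-replicate random GTR+Gamma models, estimates each ML quartet with the
package's engine (duplicate-sequence reduction included), and prints the
proportion of replicates supporting the attraction tree (S1,S3|S2,S4).
"""

from sba.experiments import ScenarioConfig, run_gene_tree_scenario

for name, label in (("star1", "short tips 0.0001"), ("star2", "tips 0.1")):
    config = ScenarioConfig(name=name, lengths=(100, 500), n_reps=50, seed=7)
    result = run_gene_tree_scenario(config)
    print(f"{name} ({label}):")
    for K in config.lengths:
        p = result.proportion(K, "T2")
        se = result.proportions.query("length == @K and category == 'T2'")["se"].iloc[0]
        print(f"  K={K:4d}  P(S1,S3 grouped) = {p:.2f} +/- {se:.2f}")

print(
    "\nA star tree carries no grouping signal, so a fair estimate would be 1/3.\n"
    "With 0.0001 tips the attraction sharpens with sequence length (S1 and S3\n"
    "remain identical while the others accumulate private substitutions); with\n"
    "0.1 tips it fades toward 1/3 as genuine signal replaces resolved ties."
)
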