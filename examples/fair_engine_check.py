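"""Engine fairness on information-free inputs.

Identical and saturated sequences carry no topology signal, so a fair ML
engine must return the three quartet topologies uniformly.  This runs the
exhaustive quartet engine with seeded random tie resolution and tests the
frequencies against (1/3, 1/3, 1/3) with the exact multinomial test.
"""

from sba.experiments import ScenarioConfig, run_noninformative_scenario

for name in ("identical", "saturated"):
    config = ScenarioConfig(name=name, lengths=(200,), n_reps=60, seed=3)
    result = run_noninformative_scenario(config)
    df = result.proportions
    props = {c: result.proportion(200, c) for c in ("T1", "T2", "T3")}
    p_value = df["p_value"].iloc[0]
    print(f"{name}: " + "  ".join(f"{k}={v:.2f}" for k, v in props.items())
          + f"  multinomial-test p = {p_value:.3f}")

print(
    "\nNeither scenario rejects uniformity: the engine itself is fair, so the\n"
    "attraction seen in the scenario simulations comes from the data-driven\n"
    "resolution of likelihood ties (duplicate-sequence grouping), not from a\n"
    "hidden preference of the likelihood machinery."
)
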