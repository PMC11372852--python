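"""Exact site-pattern theory for a 4-taxon star tree with two short branches.

Computes the 15 pattern-class probabilities for the star tree
(S1:0.0001, S2:0.01, S3:0.0001, S4:0.01), the informative mass lambda, the
short-branch inequalities, and the exact finite-length distribution of the
ML quartet topology.
"""

from sba.pattern_theory import (
    INFORMATIVE,
    PatternClass,
    check_sd1_inequalities,
    exact_mle_distribution,
    prob_resolved,
    star_class_probs,
)

tips = (0.0001, 0.01, 0.0001, 0.01)  # S1, S2, S3, S4
probs = star_class_probs(*tips)

print("Star tree (S1:0.0001, S2:0.01, S3:0.0001, S4:0.01), JC69")
print(f"informative classes: xxyy={probs[PatternClass.XXYY]:.3e} "
      f"xyxy={probs[PatternClass.XYXY]:.3e} xyyx={probs[PatternClass.XYYX]:.3e}")
print(f"lambda (P of an informative site) = {probs.lam:.3e}")
for K in (100, 1000, 100000):
    print(f"  P(at least one informative site in {K} sites) = {prob_resolved(probs.lam, K):.4f}")

report = check_sd1_inequalities(*tips)
print("uninformative mass exceeds informative mass:",
      report["uninformative_exceeds_informative"],
      f"(margin {report['uninformative_margin']:.4f})")

print("\nExact ML-topology distribution (count-argmax over informative sites):")
for K in (1, 50, 200):
    dist = exact_mle_distribution(probs, K, tie_rule="star")
    line = "  K=%-4d " % K + "  ".join(f"{t.value}={p:.4f}" for t, p in dist.items())
    print(line)

print(
    "\nThe xyxy class (grouping the two short-branch taxa S1, S3) dominates the\n"
    "informative mass, so whenever an alignment is resolved at all, it is\n"
    "overwhelmingly resolved toward the wrong tree (S1,S3|S2,S4) — but at these\n"
    "branch lengths most short alignments contain no informative site, so the\n"
    "bias of real programs is driven by how they resolve likelihood ties."
)
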