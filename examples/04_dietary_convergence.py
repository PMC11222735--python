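"""Dietary convergence across resource-pulse periods.

Filters pseudo-replicated scats, builds per-individual diet profiles
over the four core foods within each 6-week period, computes pairwise
Bray-Curtis dissimilarity between individuals, and compares periods with
Kruskal-Wallis plus Dunn/Bonferroni tests.  Lower dissimilarity during a
pulse means individuals converged on the pulsed food.
"""

from scatpulse import default_config, run_all

res = run_all(default_config(), seed=1)

print("mean pairwise Bray-Curtis dissimilarity per 6-week period")
print("(0 identical diets, 1 disjoint; winter is the pulse-free control):")
print(res.period_means.round(3).to_string(index=False))

tests = res.period_tests
print(f"\nKruskal-Wallis H = {tests['kruskal_h'].iloc[0]:.1f}, "
      f"p = {tests['kruskal_p'].iloc[0]:.2g}")
print("Dunn pairwise comparisons (Bonferroni-adjusted):")
print(tests[["group_a", "group_b", "z", "p_bonferroni"]]
      .round(3).to_string(index=False))
print("\nNote: pairwise dissimilarities share individuals and are not "
      "independent; scatpulse.convergence.disjoint_pair_dissimilarity "
      "offers a calibrated (conservative) alternative.")
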