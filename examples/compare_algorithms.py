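"""Nonparametric comparison battery on the bundled reference results.

Loads the shipped 10-function x 11-algorithm mean-results table, ranks the
algorithms per function (Friedman), refines with the Iman-Davenport F, and
runs Holm's step-down against the enhanced optimizer as control.  Small
p-values mean the control's rank advantage over that competitor is unlikely
under the null of equivalent performance.
"""

from hawkopt import friedman, holm_stepdown, iman_davenport, load_published_means

table = load_published_means()
fr = friedman(table)

print("average ranks (lower is better):")
for name, rank in fr.average_ranks.sort_values().items():
    print(f"  {name:6s} {rank:5.2f}")
print(f"Friedman chi2 = {fr.chi_square:.3f}  "
      f"(critical {fr.critical_value(0.05):.3f} at alpha=0.05)")
f_id, crit = iman_davenport(fr)
print(f"Iman-Davenport F = {f_id:.3f}  (critical {crit:.3f})")

print("\nHolm step-down vs eHHO:")
for row in holm_stepdown(fr, "eHHO", alphas=(0.05, 0.1), k_comparisons=10):
    verdict = "reject" if row.reject[0.05] else "keep"
    print(f"  {row.comparison:16s} p={row.p_value:9.3g}  "
          f"threshold={row.thresholds[0.05]:.6f}  H0 {verdict}")
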