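"""How common is bistability in random mRNA-miRNA kinetics?

Samples complex-degradation multipliers uniformly from (0.125, 16) for
the two- and three-site circuits and classifies each set by the
closed-form non-monotonicity test of the steady-state curve.
"""

import numpy as np

from mirswitch import analytic_condition, run_screen

for sites in (2, 3):
    summary = run_screen(n_sites=sites, n=2000, seed=0)
    pct = 100 * summary.fraction_bistable
    se = 100 * summary.binomial_se
    print(f"{sites}-site circuit: {summary.n_bistable}/{summary.n_total} bistable "
          f"({pct:.1f}% +/- {se:.1f}%)")

summary = run_screen(n_sites=2, n=2000, seed=0)
bi = [r for r in summary.records if r.bistable]
drops = np.array([r.free_mrna_drop_log10 for r in bi])
totals = np.array([abs(r.total_mrna_change_log10) for r in bi])
print(f"median free-mRNA drop: 10^{np.median(drops):.2f}")
print(f"median |total-mRNA change|: 10^{np.median(totals):.2f}")
assert all(analytic_condition(r.params) for r in bi)
print("every bistable set satisfies a1/b1 < a2/(2 b2) -- the closed-form requirement")
print(
    "Interpretation: roughly a third (two sites) to a half (three sites) of random\n"
    "kinetics support a switch, which flips free mRNA by orders of magnitude while\n"
    "leaving total mRNA nearly unchanged."
)
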