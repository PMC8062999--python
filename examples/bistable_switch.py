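"""A two-site mRNA-miRNA circuit acting as a bistable switch.

Builds the representative "cooperative mRNA degradation" parameter set
(the mRNA in the 1:2 complex degrades 10x faster than free mRNA), traces
its bifurcation diagram in the miRNA synthesis rate, and inspects the
three fixed points inside the bistable window.
"""

from mirswitch import MmiParameters, bifurcation_diagram, classify_bistable, steady_states_at

p = MmiParameters(n_sites=2, a=(1.0, 10.0), b=(1.0, 1.0), K_scaled=1e-5)

rec = classify_bistable(p)
lo, hi = rec.fold_controls
print(f"bistable: {rec.bistable}")
print(f"bistable window of the miRNA synthesis rate: ({lo:.4f}, {hi:.4f})")
print(f"free-mRNA drop across the switch: 10^{rec.free_mrna_drop_log10:.2f}")
print(f"total-mRNA change across the switch: 10^{rec.total_mrna_change_log10:.2f}")

mid = 0.5 * (lo + hi)
print(f"\nfixed points at s_r = {mid:.4f}:")
for s in steady_states_at(p, mid):
    print(
        f"  {s.stability:22s} free mRNA = {s.full.R:.3e}  total mRNA = {s.reduced.R_T:.3f}"
    )

diag = bifurcation_diagram(p, control_range=(0.0, 1.0), resolution=200)
print(f"\ndiagram: {len(diag.branches)} branches, {len(diag.folds)} saddle-node folds")
print(
    "Interpretation: inside the window two stable states coexist -- a free-mRNA-high\n"
    "and a free-mRNA-low state separated by a saddle -- although total mRNA barely\n"
    "changes; the switch lives almost entirely at the free/complexed level."
)
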