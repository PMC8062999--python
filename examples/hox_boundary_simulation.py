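"""Hoxa5/Hoxc8 boundary formation on a 10 x 40 cell grid.

Simulates the titration (mmi_S) model under transient, noisy antiparallel
RA/FGF gradients, then repeats with miR-27 or miR-196 silenced, and
prints fate maps and boundary metrics.
"""

import numpy as np

from mirswitch.tissue import (
    MorphogenConfig,
    boundary_position,
    cell_model,
    default_initial,
    fate_call,
    knockout,
    make_morphogen_field,
    mrna_overlap_band,
    simulate_tissue,
    transition_width,
)
from mirswitch.tissue.metrics import MMI_S_THRESHOLDS

cfg = MorphogenConfig()


def run(spec, seed=1):
    field = make_morphogen_field(cfg, seed=seed)
    init = default_initial(spec)
    grid = {k: np.full((cfg.n_columns, cfg.n_positions), v) for k, v in init.items()}
    return simulate_tissue(spec, field, t_end=80.0, dt=0.01, seed=seed, initial=grid)


wt = cell_model("mmi_S")
for name, spec in (
    ("wild type", wt),
    ("miR-27 knockout", knockout(wt, "miR-27")),
    ("miR-196 knockout", knockout(wt, "miR-196")),
):
    traj = run(spec)
    Pa, Pc = traj.final["Pa"], traj.final["Pc"]
    call = fate_call(Pa, Pc, MMI_S_THRESHOLDS)
    counts = {
        lab: call.count(lab)
        for lab in ("A5on_C8off", "A5off_C8on", "double_on", "double_off")
    }
    print(f"{name}:")
    print(f"  fate counts (400 cells): {counts}")
    print(f"  boundary position: {boundary_position(Pa, Pc, MMI_S_THRESHOLDS):.1f}")
    print(f"  transition width: {transition_width(Pa, Pc, MMI_S_THRESHOLDS)} positions")
    if name == "wild type":
        band = np.where(mrna_overlap_band(traj.final["Ra"], traj.final["Rc"], absolute=0.2))[0]
        print(f"  total-mRNA overlap band: positions {band.min()}..{band.max()}")

print(
    "\nInterpretation: proteins segregate into rostral Hoxa5 and caudal Hoxc8 blocks\n"
    "with no double-positive cell even though the total mRNAs overlap around the\n"
    "boundary; silencing miR-27 de-represses caudal Hoxa5 (hybrid cells), and\n"
    "silencing miR-196 lets Hoxc8 switch on at lower FGF, pulling the boundary\n"
    "rostrally."
)
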