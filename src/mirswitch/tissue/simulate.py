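"""Stochastic tissue simulation on the rostrocaudal cell grid.

Cells are autonomous (no coupling between neighbours); all of them read
the same deterministic morphogen backbone through independent per-cell
noise processes.  Integration is Euler-Maruyama with a fixed step,
clipping species at zero; the fast binding equilibria of titration pairs
are re-solved at every step by warm-started Newton iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import CellModelSpec
from .morphogen import MorphogenConfig, MorphogenField, make_morphogen_field

__all__ = ["TissueTrajectory", "simulate_tissue", "simulate_single_cell"]


@dataclass
class TissueTrajectory:
    spec: CellModelSpec
    field: MorphogenField
    times: np.ndarray
    snapshots: list[dict[str, np.ndarray]]  # species -> (n_columns, n_positions)

    @property
    def final(self) -> dict[str, np.ndarray]:
        return self.snapshots[-1]

    def free_final(self) -> dict[str, np.ndarray]:
        return self.spec.free_species(self.final)

    def to_frame(self):
        import pandas as pd

        rows = []
        for t, snap in zip(self.times, self.snapshots):
            for name, arr in snap.items():
                nc, npos = arr.shape
                for col in range(nc):
                    for pos in range(npos):
                        rows.append((t, col, pos, name, arr[col, pos]))
        return pd.DataFrame(rows, columns=["time", "column", "position", "species", "value"])


def simulate_tissue(
    spec: CellModelSpec,
    field: MorphogenField | None = None,
    t_end: float = 80.0,
    dt: float = 0.01,
    seed: int = 0,
    snapshot_times: tuple[float, ...] | None = None,
    initial: dict[str, np.ndarray] | None = None,
) -> TissueTrajectory:
    """Integrate every cell of the grid under the noisy morphogen field.

    Raises a ``FloatingPointError`` naming the first offending time if
    the state leaves the finite range (numerical instability).
    """
    if field is None:
        field = make_morphogen_field(MorphogenConfig(), seed=seed)
    field.reset_noise(seed)
    shape = (field.cfg.n_columns, field.cfg.n_positions)
    state = {
        s: (np.zeros(shape) if initial is None else np.array(initial[s], dtype=float))
        for s in spec.species
    }
    cache: dict = {}
    n_steps = int(round(t_end / dt))
    snap_at = sorted(snapshot_times) if snapshot_times else [t_end]
    times, snaps = [], []
    next_snap = 0

    t = 0.0
    for step in range(n_steps + 1):
        if next_snap < len(snap_at) and t >= snap_at[next_snap] - 0.5 * dt:
            times.append(t)
            snaps.append({k: v.copy() for k, v in state.items()})
            next_snap += 1
        if step == n_steps:
            break
        ra, fgf = field.perceived(t)
        d = spec.rhs(state, ra, fgf, cache)
        for s in state:
            state[s] = np.maximum(state[s] + dt * d[s], 0.0)
            if not np.all(np.isfinite(state[s])):
                bad = np.argwhere(~np.isfinite(state[s]))[0]
                raise FloatingPointError(
                    f"instability in species {s} at t={t:.3f}, cell {tuple(bad)}"
                )
        field.step_noise(dt)
        t += dt

    if not snaps or times[-1] < t_end - dt:
        times.append(t)
        snaps.append({k: v.copy() for k, v in state.items()})
    return TissueTrajectory(spec=spec, field=field, times=np.asarray(times), snapshots=snaps)


def simulate_single_cell(
    spec: CellModelSpec,
    ra_of_t,
    fgf_of_t,
    t_end: float = 120.0,
    dt: float = 0.01,
    initial: dict[str, float] | None = None,
    record_every: int = 50,
):
    """Deterministic single-cell time course under prescribed signals.

    ``ra_of_t``/``fgf_of_t`` are callables of time.  Returns (times,
    trajectory dict of 1-d arrays).
    """
    state = {s: np.array([float((initial or {}).get(s, 0.0))]) for s in spec.species}
    cache: dict = {}
    n_steps = int(round(t_end / dt))
    times, traj = [], {s: [] for s in spec.species}
    for step in range(n_steps + 1):
        t = step * dt
        if step % record_every == 0 or step == n_steps:
            times.append(t)
            for s in spec.species:
                traj[s].append(float(state[s][0]))
        if step == n_steps:
            break
        ra = np.array([float(ra_of_t(t))])
        fgf = np.array([float(fgf_of_t(t))])
        d = spec.rhs(state, ra, fgf, cache)
        for s in state:
            state[s] = np.maximum(state[s] + dt * d[s], 0.0)
    return np.asarray(times), {s: np.asarray(v) for s, v in traj.items()}
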