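"""Reproducible experiment runner: config in, tables + JSON + log out.

Every run writes, into its output directory, the tables/summaries of the
requested experiment together with an echo of the fully-resolved config
(including the master seed and package version), so a directory is
self-describing and regenerable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__

log = logging.getLogger("mirswitch")

EXPERIMENTS = (
    "screen",
    "bifurcate",
    "phase-plane",
    "simulate-tissue",
    "enumerate-sites",
    "crnt",
    "ra-pulse",
    "fixtures",
)


class ConfigError(ValueError):
    """Config rejected before any computation."""


@dataclass
class RunConfig:
    experiment: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "mirswitch_out"

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed must be a nonnegative integer, got {self.seed!r}")
        for key, value in self.params.items():
            if key.endswith(("rate", "_R", "_r")) or key in ("K_scaled",):
                if isinstance(value, (int, float)) and value < 0:
                    raise ConfigError(f"parameter {key}={value} must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def _dump_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")


def run_experiment(config: RunConfig) -> Path:
    """Dispatch a validated config and write its result bundle."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        log.info(
            "experiment=%s seed=%d version=%s", config.experiment, config.seed, __version__
        )
        summary = _DISPATCH[config.experiment](config, out)
        summary.update(
            experiment=config.experiment,
            seed=config.seed,
            version=__version__,
            runtime_s=round(time.time() - t0, 2),
        )
        _dump_json(summary, out / "summary.json")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh)
        log.info("done in %.1fs", time.time() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _exp_screen(config: RunConfig, out: Path) -> dict:
    from .screen import run_screen

    p = config.params
    summary = run_screen(
        n_sites=int(p.get("sites", 2)),
        n=int(p.get("n", 10_000)),
        seed=config.seed,
        control_range=tuple(p["control_range"]) if "control_range" in p else None,
    )
    summary.to_frame().to_csv(out / "screen.csv", index=False)
    return dict(
        n_total=summary.n_total,
        n_bistable=summary.n_bistable,
        fraction_bistable=summary.fraction_bistable,
        binomial_se=summary.binomial_se,
    )


def _exp_bifurcate(config: RunConfig, out: Path) -> dict:
    from .parameters import MmiParameters
    from .steady_state import bifurcation_diagram
    from .synthetic import fixture

    p = dict(config.params)
    name = p.pop("fixture", None)
    rng = tuple(p.pop("control_range", (0.0, 4.0)))
    res = int(p.pop("resolution", 400))
    params = fixture(name) if name else MmiParameters(**p)
    diagram = bifurcation_diagram(params, control_range=rng, resolution=res)
    diagram.to_frame().to_csv(out / "bifurcation.csv", index=False)
    if config.params.get("plot"):
        _plot_bifurcation(diagram, out / "bifurcation.png")
    return dict(
        bistable=diagram.bistable,
        bistable_interval=list(diagram.bistable_interval) if diagram.bistable else None,
        n_folds=len(diagram.folds),
    )


def _plot_bifurcation(diagram, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for branch in diagram.branches:
        xs = [c for c, _ in branch]
        ys = [rec.full.R for _, rec in branch]
        stable = branch[0][1].stable
        ax.plot(xs, ys, "-" if stable else "--", lw=1.5)
    ax.set_yscale("log")
    ax.set_xlabel("miRNA synthesis rate $s_r$")
    ax.set_ylabel("free mRNA")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _exp_phase_plane(config: RunConfig, out: Path) -> dict:
    import pandas as pd

    from .parameters import MmiParameters
    from .steady_state import phase_plane
    from .synthetic import fixture

    p = dict(config.params)
    name = p.pop("fixture", None)
    control = p.pop("control", None)
    params = fixture(name) if name else MmiParameters(**p)
    pp = phase_plane(params, control=control)
    pd.DataFrame(pp.nullcline_R, columns=["R_T", "r_T"]).to_csv(
        out / "nullcline_RT.csv", index=False
    )
    pd.DataFrame(pp.nullcline_r, columns=["R_T", "r_T"]).to_csv(
        out / "nullcline_rT.csv", index=False
    )
    pd.DataFrame(pp.separatrix, columns=["R_T", "r_T"]).to_csv(
        out / "separatrix.csv", index=False
    )
    return dict(
        n_steady_states=len(pp.steady_states),
        n_stable=sum(s.stable for s in pp.steady_states),
        status=pp.status,
    )


def _exp_tissue(config: RunConfig, out: Path) -> dict:
    import numpy as np

    from .tissue import (
        MorphogenConfig,
        cell_model,
        default_initial,
        fate_call,
        make_morphogen_field,
        simulate_tissue,
        transition_width,
    )
    from .tissue.metrics import MMI_S_THRESHOLDS, FateThresholds

    p = config.params
    spec = cell_model(p.get("model", "mmi_S"))
    for ko in p.get("ko", []) if isinstance(p.get("ko"), list) else filter(None, [p.get("ko")]):
        spec = spec.knockout(ko)
    cfg = MorphogenConfig(**p.get("morphogens", {}))
    field = make_morphogen_field(cfg, seed=config.seed)
    init = default_initial(spec)
    shape = (cfg.n_columns, cfg.n_positions)
    traj = simulate_tissue(
        spec,
        field,
        t_end=float(p.get("t_end", 80.0)),
        dt=float(p.get("dt", 0.01)),
        seed=config.seed,
        initial={k: np.full(shape, v) for k, v in init.items()},
    )
    traj.to_frame().to_csv(out / "species.csv", index=False)
    th = MMI_S_THRESHOLDS if spec.variant.startswith("mmi") else FateThresholds()
    call = fate_call(traj.final["Pa"], traj.final["Pc"], th)
    np.savetxt(out / "fates.txt", call.labels, fmt="%s")
    return dict(
        model=spec.variant,
        transition_width=transition_width(traj.final["Pa"], traj.final["Pc"], th),
        counts={
            lab: call.count(lab)
            for lab in ("A5on_C8off", "A5off_C8on", "double_on", "double_off")
        },
        theta_a=call.theta_a,
        theta_c=call.theta_c,
    )


def _exp_sites(config: RunConfig, out: Path) -> dict:
    from .motifs import count_motifs, read_site_catalog

    p = config.params
    if "path" not in p:
        raise ConfigError("enumerate-sites requires params.path (TSV site table)")
    cat = read_site_catalog(p["path"], dialect=p.get("dialect"))
    k = int(p.get("k", 2))
    counts = count_motifs(cat, k)
    per_gene = (
        cat.frame.groupby(["gene_id", "mirna_family"]).size().rename("n_sites").reset_index()
    )
    per_gene.to_csv(out / "per_gene.csv", index=False)
    return dict(
        k=k,
        n_rows=len(cat),
        n_rejected=cat.n_rejected,
        pair_count_lower=counts.pair_count_lower,
        tuple_count_upper=counts.tuple_count_upper,
    )


def _exp_crnt(config: RunConfig, out: Path) -> dict:
    from .crnt import build_network, deficiency

    n = int(config.params.get("sites", 1))
    net = build_network(n)
    rep = deficiency(net)
    theorem = (
        "deficiency zero theorem applies"
        if rep.deficiency == 0
        else "deficiency one theory applies"
        if rep.deficiency == 1
        else "deficiency > 1: neither elementary theorem applies"
    )
    return dict(
        n_sites=n,
        n_complexes=rep.n_complexes,
        n_linkage_classes=rep.n_linkage_classes,
        stoich_rank=rep.stoich_rank,
        deficiency=rep.deficiency,
        weakly_reversible=rep.weakly_reversible,
        theorem=theorem,
    )


def _exp_ra_pulse(config: RunConfig, out: Path) -> dict:
    from .tissue import cell_model, ra_pulse_experiment

    p = config.params
    spec = cell_model(p.get("model", "mmi_S"))
    res = ra_pulse_experiment(
        spec,
        ra_high=float(p.get("ra_high", 1.0)),
        ra_low=float(p.get("ra_low", 0.005)),
        t_switch=float(p.get("t_switch", 60.0)),
        mir27_active=bool(p.get("mir27_active", True)),
    )
    np.savetxt(out / "pa_trace.csv", np.c_[res.times, res.pa_trace], delimiter=",")
    return dict(
        pa_pulsed=res.pa_pulsed,
        pa_unpulsed=res.pa_unpulsed,
        persistent=res.persistent,
        on_threshold=res.on_threshold,
        above_threshold=res.above_threshold,
        bistable_window=list(res.bistable_window) if res.bistable_window else None,
    )


def _exp_fixtures(config: RunConfig, out: Path) -> dict:
    from .motifs import write_site_catalog
    from .parameters import MmiParameters, save_parameters
    from .synthetic import fixture, fixture_names

    written = []
    for name in fixture_names():
        obj = fixture(name)
        if isinstance(obj, MmiParameters):
            save_parameters(obj, out / f"{name}.yaml")
        elif isinstance(obj, dict) and "catalog" in obj:
            write_site_catalog(obj["catalog"], out / f"{name}.tsv")
            _dump_json(
                {str(k): dataclasses.asdict(v) for k, v in obj["truth"].items()},
                out / f"{name}_truth.json",
            )
        else:
            serializable = {
                k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else str(v))
                for k, v in obj.items()
            }
            _dump_json(serializable, out / f"{name}.json")
        written.append(name)
    return dict(fixtures=written)


_DISPATCH = {
    "screen": _exp_screen,
    "bifurcate": _exp_bifurcate,
    "phase-plane": _exp_phase_plane,
    "simulate-tissue": _exp_tissue,
    "enumerate-sites": _exp_sites,
    "crnt": _exp_crnt,
    "ra-pulse": _exp_ra_pulse,
    "fixtures": _exp_fixtures,
}
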