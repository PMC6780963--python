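"""Configuration, canonical scenarios and the batch runner.

Everything in the model is deterministic — there is no random number
generation anywhere, so no seed plumbing is exposed; rerunning any
scenario or batch reproduces its outputs byte for byte.

Configuration is TOML. An empty (or missing) file yields the complete
default profile: EMT6/Ro nutrient/kinetic constants, water at 37 °C,
and the default chip geometry. Values may be bare numbers (interpreted
in the key's declared unit, micrometres for ``*_um`` keys and so on) or
strings with explicit units ("0.8 mM", "24.3 um").
"""

from __future__ import annotations

import importlib.resources
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_core import (
    FluidProps,
    KineticParams,
    Nutrient,
    NutrientSpec,
)
from .chip.geometry import ChannelSpec, TrapKind, TrapSpec
from .units import UM, parse_quantity

__all__ = [
    "Config",
    "ConfigError",
    "Scenario",
    "SweepSpec",
    "load_config",
    "dump_config",
    "paper_scenarios",
    "run_batch",
]

# declared unit per leaf key (None = SI / dimensionless as stored)
_SCHEMA: dict[str, dict[str, str | None]] = {
    "nutrient.glucose": dict(
        D_tissue="m2/s", D_medium="m2/s", Vmax="mol/m3/s",
        Km="mM", C_crit="mM", C_bulk="mM",
    ),
    "nutrient.oxygen": dict(
        D_tissue="m2/s", D_medium="m2/s", Vmax="mol/m3/s",
        Km="mM", C_crit="mM", C_bulk="mM",
    ),
    "kinetics": dict(A="1/h", Ap="1/s", An="1/s"),
    "fluid": dict(density="kg/m3", viscosity="Pa.s"),
    "channel": dict(length_um="um", width_um="um", height_um="um"),
    "trap": dict(
        kind=None, length_um="um", width_um="um", height_um="um", wall_um="um"
    ),
    "simulation": dict(
        mode=None, initial_radius_um="um", horizon_h="h", dt_h="h",
        resolution_um="um", flow_ul_min="uL/min", n_nodes=None,
    ),
}

_SIM_DEFAULTS = {
    "mode": "static",
    "initial_radius_um": 24.3 * UM,
    "horizon_h": 550.0,
    "dt_h": 20.0,
    "resolution_um": 30.0 * UM,
    "flow_ul_min": 5.0 * 1e-9 / 60.0,
    "n_nodes": 256,
}


class ConfigError(ValueError):
    """Invalid configuration; message lists every violation found."""


@dataclass
class Config:
    """Validated full configuration, all values in internal units."""

    glucose: NutrientSpec
    oxygen: NutrientSpec
    kinetics: KineticParams
    fluid: FluidProps
    channel: ChannelSpec
    trap: TrapSpec
    simulation: dict

    @property
    def specs(self) -> tuple[NutrientSpec, NutrientSpec]:
        return (self.glucose, self.oxygen)


def _package_defaults() -> dict:
    data = importlib.resources.files("avatum").joinpath("data")
    merged: dict = {}
    for name in ("emt6ro.toml", "fig2_default.toml"):
        with data.joinpath(name).open("rb") as fh:
            _deep_update(merged, tomllib.load(fh))
    return merged


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def _flatten(table: dict, prefix: str = "") -> dict[str, object]:
    out = {}
    for k, v in table.items():
        key = f"{prefix}.{k}" if prefix else k
        if isinstance(v, dict):
            out.update(_flatten(v, key))
        else:
            out[key] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> Config:
    """Load, merge with defaults, normalize units, and validate.

    ``overrides`` is a flat {"table.key": value} mapping applied last
    (the scenario mechanism). All violations are reported at once.
    """
    raw = _package_defaults()
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        _deep_update(raw, user)
    flat = _flatten(raw)
    if overrides:
        for k, v in overrides.items():
            flat[k] = v

    errors: list[str] = []
    values: dict[str, dict] = {t: {} for t in _SCHEMA}
    for key, v in flat.items():
        table, _, leaf = key.rpartition(".")
        if table not in _SCHEMA or leaf not in _SCHEMA[table]:
            errors.append(f"unknown key {key!r}")
            continue
        unit = _SCHEMA[table][leaf]
        if unit is None:
            values[table][leaf] = v
        else:
            try:
                values[table][leaf] = parse_quantity(v, default_unit=unit)
            except (ValueError, KeyError) as exc:
                errors.append(f"{key}: {exc}")
    # fill simulation defaults
    sim = dict(_SIM_DEFAULTS)
    sim.update(values["simulation"])

    def build(factory, table, **kw):
        try:
            return factory(**values[table], **kw)
        except (TypeError, ValueError) as exc:
            errors.append(f"[{table}] {exc}")
            return None

    glucose = build(NutrientSpec, "nutrient.glucose", name=Nutrient.GLUCOSE)
    oxygen = build(NutrientSpec, "nutrient.oxygen", name=Nutrient.OXYGEN)
    kinetics = build(KineticParams, "kinetics")
    fluid = build(FluidProps, "fluid")
    channel = None
    trap = None
    try:
        ch = values["channel"]
        channel = ChannelSpec(ch["length_um"], ch["width_um"], ch["height_um"])
    except (KeyError, ValueError) as exc:
        errors.append(f"[channel] {exc}")
    try:
        tr = values["trap"]
        kind = TrapKind(tr.get("kind", "u_barrier"))
        trap = TrapSpec(kind, tr["length_um"], tr["width_um"], tr["height_um"], tr["wall_um"])
    except (KeyError, ValueError) as exc:
        errors.append(f"[trap] {exc}")
    if sim["mode"] not in ("static", "chip"):
        errors.append(f"[simulation] mode must be 'static' or 'chip', got {sim['mode']!r}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return Config(
        glucose=glucose, oxygen=oxygen, kinetics=kinetics, fluid=fluid,
        channel=channel, trap=trap, simulation=sim,
    )


def dump_config(cfg: Config) -> str:
    """Serialize a Config back to TOML (inverse of :func:`load_config`)."""
    def um(x):
        return x / UM

    tables: dict[str, dict] = {
        "nutrient.glucose": _nutrient_table(cfg.glucose),
        "nutrient.oxygen": _nutrient_table(cfg.oxygen),
        "kinetics": dict(A=cfg.kinetics.A, Ap=cfg.kinetics.Ap, An=cfg.kinetics.An),
        "fluid": dict(density=cfg.fluid.density, viscosity=cfg.fluid.viscosity),
        "channel": dict(
            length_um=um(cfg.channel.length),
            width_um=um(cfg.channel.width),
            height_um=um(cfg.channel.height),
        ),
        "trap": dict(
            kind=cfg.trap.kind.value,
            length_um=um(cfg.trap.length),
            width_um=um(cfg.trap.width),
            height_um=um(cfg.trap.height),
            wall_um=um(cfg.trap.wall),
        ),
        "simulation": dict(
            mode=cfg.simulation["mode"],
            initial_radius_um=um(cfg.simulation["initial_radius_um"]),
            horizon_h=cfg.simulation["horizon_h"],
            dt_h=cfg.simulation["dt_h"],
            resolution_um=um(cfg.simulation["resolution_um"]),
            flow_ul_min=cfg.simulation["flow_ul_min"] / (1e-9 / 60.0),
            n_nodes=cfg.simulation["n_nodes"],
        ),
    }
    lines = []
    for tname, table in tables.items():
        lines.append(f"[{tname}]")
        for k, v in table.items():
            if isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{k} = {str(v).lower()}")
            elif isinstance(v, int):
                lines.append(f"{k} = {v}")
            else:
                lines.append(f"{k} = {float(v)!r}")
        lines.append("")
    return "\n".join(lines)


def _nutrient_table(spec: NutrientSpec) -> dict:
    return dict(
        D_tissue=spec.D_tissue, D_medium=spec.D_medium, Vmax=spec.Vmax,
        Km=spec.Km, C_crit=spec.C_crit, C_bulk=spec.C_bulk,
    )


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class Scenario:
    """One labelled run: a mode plus overrides of the base config."""

    label: str
    mode: str  # "static" | "chip"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        valid = set()
        for table, leaves in _SCHEMA.items():
            for leaf in leaves:
                valid.add(f"{table}.{leaf}")
        bad = [k for k in self.overrides if k not in valid]
        if bad:
            raise ConfigError(f"scenario {self.label!r}: unknown override(s) {bad}")


@dataclass
class SweepSpec:
    """Cross-product (or zipped) parameter sweep definition."""

    axes: list[tuple[str, list]]
    cross_product: bool = True
    max_size: int = 100

    def scenarios(self, mode: str, prefix: str = "sweep") -> list[Scenario]:
        if not self.axes:
            raise ConfigError("sweep needs at least one axis")
        if self.cross_product:
            grids = np.meshgrid(*[np.arange(len(v)) for _, v in self.axes], indexing="ij")
            combos = np.stack([g.ravel() for g in grids], axis=1)
        else:
            n = len(self.axes[0][1])
            combos = np.tile(np.arange(n)[:, None], (1, len(self.axes)))
        if len(combos) > self.max_size:
            raise ConfigError(
                f"sweep of {len(combos)} scenarios exceeds cap {self.max_size}; "
                "raise max_size explicitly to allow it"
            )
        out = []
        for row in combos:
            ov = {name: vals[i] for (name, vals), i in zip(self.axes, row)}
            label = prefix + "_" + "_".join(
                f"{name.split('.')[-1]}={vals[i]}" for (name, vals), i in zip(self.axes, row)
            )
            out.append(Scenario(label=label, mode=mode, overrides=ov))
        labels = [s.label for s in out]
        if len(set(labels)) != len(labels):
            raise ConfigError("sweep produced duplicate labels")
        return out


# canonical experiment grids
FIG4A_OXYGEN_MM = [0.22, 0.26, 0.30, 0.34]
FIG4A_GLUCOSE_MM = [0.6, 0.7, 0.8, 0.9, 1.0]
FIG4B_RADII_UM = [8.1, 16.2, 24.3, 32.4, 40.5, 48.6]
FIG6_FLOWS_UL_MIN = [0.5, 5.0, 50.0]


def paper_scenarios() -> list[Scenario]:
    """The canonical scenario set covering every reported experiment.

    Static medium: the 550 h nutrient-concentration sweep (oxygen
    0.22–0.34 mM x glucose 0.6–1.0 mM at R0 = 24.286 um), the initial
    radius sweep (8.1–48.6 um), and the 0.8 mM glucose / 0.28 mM
    oxygen baseline. Perfused chip: the 300 h flow-rate sweep (0.5, 5,
    50 uL/min in the U-barrier) and the U-barrier vs microwell
    comparison at 5 uL/min.
    """
    scens: list[Scenario] = []
    for o2 in FIG4A_OXYGEN_MM:
        for glc in FIG4A_GLUCOSE_MM:
            scens.append(Scenario(
                label=f"fig4a_glc={glc}_o2={o2}",
                mode="static",
                overrides={
                    "nutrient.glucose.C_bulk": glc,
                    "nutrient.oxygen.C_bulk": o2,
                    "simulation.initial_radius_um": 24.286,
                    "simulation.horizon_h": 550.0,
                },
            ))
    for r in FIG4B_RADII_UM:
        scens.append(Scenario(
            label=f"fig4b_R0={r}",
            mode="static",
            overrides={
                "nutrient.glucose.C_bulk": 0.6,
                "nutrient.oxygen.C_bulk": 0.24,
                "simulation.initial_radius_um": r,
                "simulation.horizon_h": 2400.0,
            },
        ))
    scens.append(Scenario(
        label="fig5_baseline",
        mode="static",
        overrides={"simulation.initial_radius_um": 24.3, "simulation.horizon_h": 550.0},
    ))
    for q in FIG6_FLOWS_UL_MIN:
        scens.append(Scenario(
            label=f"fig6_Q={q}",
            mode="chip",
            overrides={
                "trap.kind": "u_barrier",
                "simulation.flow_ul_min": q,
                "simulation.initial_radius_um": 24.3,
                "simulation.horizon_h": 300.0,
            },
        ))
    for kind in ("u_barrier", "microwell"):
        scens.append(Scenario(
            label=f"fig7_{kind}",
            mode="chip",
            overrides={
                "trap.kind": kind,
                "simulation.flow_ul_min": 5.0,
                "simulation.initial_radius_um": 24.3,
                "simulation.horizon_h": 300.0,
            },
        ))
    return scens


# ---------------------------------------------------------------------------
# batch runner


def run_scenario(scenario: Scenario, base_config: str | Path | None = None):
    """Run one scenario; returns (summary dict, GrowthTrajectory)."""
    from .radial_sim import simulate_static
    from .chip.simulate import simulate_perfused

    cfg = load_config(base_config, overrides=scenario.overrides)
    sim = cfg.simulation
    if scenario.mode == "static":
        traj = simulate_static(
            sim["initial_radius_um"], sim["horizon_h"], cfg.specs, cfg.kinetics,
            dt=sim["dt_h"], n_nodes=int(sim["n_nodes"]),
        )
    else:
        traj = simulate_perfused(
            cfg.trap, cfg.channel, sim["flow_ul_min"], sim["initial_radius_um"],
            sim["horizon_h"], cfg.specs, cfg.kinetics, cfg.fluid,
            dt=sim["dt_h"], resolution=sim["resolution_um"],
        )
    fin = traj.final
    trans = traj.phase_transition_times()
    summary = {
        "label": scenario.label,
        "mode": scenario.mode,
        "t_final_h": fin["t"],
        "R_final_um": fin["R"] * 1e6,
        "V_final_um3": fin["V"] * 1e18,
        "Vq_final_um3": fin["Vq"] * 1e18,
        "Vn_final_um3": fin["Vn"] * 1e18,
        "phase_final": fin["phase"],
        "t_phase2_h": trans.get(2, np.nan),
        "t_phase3_h": trans.get(3, np.nan),
    }
    if "max_shear" in fin:
        summary["max_shear_dyn_cm2"] = 10.0 * max(r["max_shear"] for r in traj.records)
    return summary, traj


def run_batch(
    scenarios: list[Scenario],
    base_config: str | Path | None = None,
    out_dir: str | Path | None = None,
    parallel_workers: int = 1,
):
    """Run scenarios sequentially (deterministic order); returns a
    summary DataFrame with one row per scenario. Individual failures
    are recorded (``error`` column) and the batch continues; callers
    treat any error row as a nonzero-exit condition.

    ``parallel_workers`` > 1 distributes scenarios over processes with
    joblib; results are re-ordered so the output is identical.
    """
    import pandas as pd

    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ConfigError("scenario labels must be unique within a batch")

    def one(s):
        try:
            summary, traj = run_scenario(s, base_config)
            return summary, traj, None
        except Exception as exc:  # recorded, batch continues
            return {"label": s.label, "mode": s.mode}, None, str(exc)

    if parallel_workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=parallel_workers)(delayed(one)(s) for s in scenarios)
    else:
        results = [one(s) for s in scenarios]

    rows = []
    for (summary, traj, err), scen in zip(results, scenarios):
        summary = dict(summary)
        summary["error"] = err if err else ""
        rows.append(summary)
        if out_dir is not None and traj is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            traj.to_dataframe().to_csv(out / f"{scen.label}.csv", index=False)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "summary.csv", index=False)
    return df
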