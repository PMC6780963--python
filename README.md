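# avatum

Deterministic simulation of **avascular tumor spheroid growth** in
static culture and in perfused microfluidic traps.

Before a tumor recruits blood vessels its growth is limited entirely by
the diffusion of nutrients from its surface. `avatum` models that
regime for spheroids of the EMT6/Ro mouse mammary carcinoma line (the
default parameter profile; everything is configurable): glucose and
oxygen diffuse into the spheroid and are consumed with Michaelis–Menten
kinetics, and the local concentrations partition the tumor into a
proliferative rim, a quiescent shell (exactly one nutrient below its
critical concentration; half uptake, no division) and a necrotic core
(both below critical; no uptake). The volume evolves by

    dV/dt = A (V − Vq) − Ap (V − Vn) − An Vn

with proliferation `A = ln 2 / 21 h`, apoptosis `Ap` acting on all
viable cells and necrosis `An` on the core (`Vq`, `Vn` are the volumes
enclosed by the quiescent and necrotic boundaries). Nutrient fields are
quasi-steady: they are re-solved at every 20 h growth step.

Two culture settings are implemented:

* **`radial_sim`** — a spherically symmetric free-boundary
  reaction–diffusion solver for a spheroid in unlimited static medium
  (surface held at the bulk concentrations).
* **`chip`** — a 3D perfused microchannel with a U-shaped barrier or a
  microwell trap: steady Stokes flow (MAC staggered grid) coupled to
  advection–diffusion of both nutrients around and through the trapped
  spheroid, including the maximum wall shear stress on the tumor
  surface at every growth step.

The package is for computational and microfluidics researchers who
want to predict spheroid growth curves, zone development and
culture-safety (shear) margins when designing perfusion experiments.

## Worked example

Grow a 24.3 µm spheroid in static medium (0.8 mM glucose, 0.28 mM
oxygen) for 200 h:

```sh
avatum static --horizon-h 200 --dt-h 20 --out traj.csv
```

prints the summary

```
label=static  mode=static  t_final_h=200.0  R_final_um=125.98161265905543
V_final_um3=8375487.587440376  Vq_final_um3=2274845.1722825416
Vn_final_um3=0.0  phase_final=2  t_phase2_h=140.0  t_phase3_h=nan
```

and `traj.csv` holds the trajectory:

```
t_h,R_um,V_um3,Vq_um3,Vn_um3,phase
0.0,24.3,60104.56109099087,0.0,0.0,1
20.0,28.771864428536013,99768.31216578225,0.0,0.0,1
...
140.0,79.2753914601141,2086910.3600257353,48585.37076117757,0.0,2
...
200.0,125.98161265905544,8375487.587440376,2274845.1722825416,0.0,2
```

Reading it: the spheroid grows exponentially (volume ×1.66 per 20 h
step, i.e. a 21 h doubling time) while it is entirely proliferative
(`phase 1`). At t = 140 h, glucose at the centre falls below its
0.06 mM critical concentration, a quiescent core appears (`Vq_um3 > 0`,
`phase 2`) and growth starts to slow; the necrotic core (`phase 3`)
forms much later. The same library calls are available in Python:

```python
from avatum import EMT6RO_GLUCOSE, EMT6RO_OXYGEN, EMT6RO_KINETICS, simulate_static
traj = simulate_static(24.3e-6, 200.0, (EMT6RO_GLUCOSE, EMT6RO_OXYGEN), EMT6RO_KINETICS)
print(traj.to_dataframe().tail(1))
```

Perfused-chip runs work the same way (`avatum chip --trap u_barrier
--flow-ul-min 5 --horizon-h 300 --out chip.csv`, optional `--vtk-out`
field snapshots for ParaView), and `avatum paper-suite --out-dir out/`
materializes and runs the whole canonical scenario set (nutrient and
initial-radius sweeps, flow-rate sweep, trap comparison) into summary
and trajectory CSVs. `avatum sweep` runs ad-hoc parameter grids.

## Layout

- `src/avatum/model_core.py` — domain types, zone classification, the
  growth law, EMT6/Ro defaults
- `src/avatum/radial_sim.py` — static-medium free-boundary solver and
  growth stepping
- `src/avatum/chip/` — trap geometry, Stokes flow, nutrient transport,
  wall shear and perfused growth
- `src/avatum/workbench.py` — TOML configuration, canonical scenarios,
  batch runner; `src/avatum/cli.py` — the `avatum` command
- `docs/methods.md` — the model, numerical methods and limitations in
  detail
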