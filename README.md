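# patchymd

Patchy-particle molecular dynamics of multivalent proteins, built to study
how valency and binding affinity organize multicomponent biomolecular
condensates — multilayered droplets (high-valency scaffolds at the core,
low-valency clients at the interface), multidroplet coexistence, surface
tensions, and species exchange kinetics.

Each protein is a pseudo-hard sphere of diameter σ carrying 2–4 attractive,
orientation-dependent binding sites (patches).  A bond between patches a
and b has well depth d_ab·ε set by a symmetric affinity matrix; a patch
engages at most one partner, so the number and strength of sites is the
protein's effective valency.  Everything is in reduced units: T* = k_BT/ε,
ρ* = Nσ³/V, t* = t√(ε/mσ²), γ in k_BT/σ².  The package bundles

- `patchymd.model` — the six-species catalog (valencies 4, 4, 3, 3, 2.25,
  2) and four mixture affinity presets (valency-driven, like-valency,
  non-competing scaffolds, competing scaffolds), YAML-serializable;
- `patchymd.engine` — rigid-body NVT/NVE MD (velocity-Verlet + quaternion
  rotation, Langevin or velocity-rescale thermostat, periodic k-d-tree
  Verlet neighbor list, numba-accelerated forces with a numpy reference
  path);
- `patchymd.coexistence` — direct-coexistence slabs, per-species density
  profiles, two-interface tanh fits, and critical points via Ising scaling
  + the law of rectilinear diameters;
- `patchymd.interfacial` — surface tension from pressure-tensor anisotropy;
- `patchymd.structure` — condensate detection (bonded-network components),
  core/shell layering profiles, exchange-rate order parameter,
  molar-fraction nucleation series, and mixture order parameters;
- `patchymd.fixtures`, `patchymd.trajio`, `patchymd.cli` — synthetic
  ground-truth trajectories, extended-XYZ/HDF5 I/O, and the `patchymd`
  command line.

See `docs/methods.md` for the model, parameters, and numerical choices.

## Worked example

Fit the critical point of the pure 4-valency promiscuous protein from
three desk-scale direct-coexistence runs:

```python
from patchymd.model import build_pure_system
from patchymd.coexistence import (init_direct_coexistence, slab_density_profile,
                                  fit_coexistence_densities, estimate_critical_point)
from patchymd.engine import Schedule, Thermostat, run

mix = build_pure_system("4v-promiscuous", 144)
points = []
for T in (0.09, 0.105, 0.12):
    state = init_direct_coexistence(mix, slab_density=0.5, seed=1, temperature=T)
    traj = run(state, mix, Schedule(dt=0.002, n_steps=200_000, snapshot_stride=2500,
                                    seed=2, thermostat=Thermostat("langevin", T, 0.5)))
    profile = slab_density_profile(traj)          # z-profile, recentered, last half
    points.append(fit_coexistence_densities(profile, temperature=T))
    print(f"T*={T}: rho_v*={points[-1].rho_vapor:.3f}  rho_l*={points[-1].rho_liquid:.3f}")
fit = estimate_critical_point(points)
print(f"Tc* = {fit.tc:.3f}  rho_c* = {fit.rho_c:.2f}")
```

which prints (about two minutes on one CPU):

```
T*=0.09: rho_v*=0.030  rho_l*=0.333
T*=0.105: rho_v*=0.024  rho_l*=0.266
T*=0.12: rho_v*=0.130  rho_l*=0.200
Tc* = 0.120  rho_c* = 0.16
```

The vapor branch fills and the density gap closes as T* approaches the
critical temperature; the gap and the mean density are then jointly fit
with the 3D-Ising exponent β = 0.325 and the law of rectilinear diameters.
At this small scale (N = 144) the fitted Tc* carries a few percent of
scatter between seeds, but orders correctly across species:
lower-valency proteins have lower critical points, and the 2-valency
protein does not phase separate at all.

The same workflow from the shell:

```sh
patchymd simulate --config run.yaml --seed 1 --out out/
patchymd analyze profile --traj out/trajectory.xyz --out profile.csv
patchymd analyze gamma --scalars out/trajectory_scalars.csv \
    --lx 6.9 --ly 6.9 --lz 27.7 --temperature 0.09
patchymd analyze orderparams --mixture valency_driven
```

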