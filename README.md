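# evosoc

Simulation toolkit for **societal transitions on an evolving support
network**: standstill, collapse and growth of a model society whose
occupations interact through a binary directed support matrix and compete
against a shared environment.

A society is `n` occupations with productivities `x_i ≥ 0` (each a proxy for
the inhabitants the occupation feeds), coupled by a 0–1 support matrix `C`
(`c_ij = 1` ⇔ occupation `j` supports occupation `i`) and governed by

    dx_i/dt = a (C x)_i / x_i − b X,      X = Σ_i x_i,

where `a` is the supporting coefficient and `b` the environmental
restriction coefficient.  For an irreducible (strongly connected) `C` the
attractor is the Perron–Frobenius eigenvector `v` of `C`, scaled so total
productivity equals `(a/b)·λ_pf` where `λ_pf` is the spectral radius.  On
top of this, occupations falling below a functioning threshold *limina* are
eliminated, and stochastic *mutation* moves limina-sized productivity quanta
between (and creates) occupations.  Scenario engines drive this system
through:

| scenario | driving force | typical outcome |
| --- | --- | --- |
| `boot` | self-boot from one self-supporting occupation | growth to full occupation at `X ≈ (a/b)λ_pf` |
| `supporting` | parasitic derived society (no back-support) | standstill with reduced share, erosion, or collapse |
| `disturbing` | one-phase restriction pulse `b → r_d·b` | losses + recovery, or wipeout at large `r_d` |
| `invading` | intact foreign society, shared environment | the larger-`λ_pf` society takes the environment |
| `mutual` | derived society supports the original back | merged society, higher equilibrium: growth |

The package is aimed at complex-systems researchers who want a small,
deterministic, fully seeded sandbox for threshold-driven extinction cascades
and structure-changing dynamics on nonnegative matrices.

## Library quick start

```python
import numpy as np
from evosoc import (InterSocietySpec, ScenarioConfig,
                    generate_support_matrix, spectral_radius_and_perron,
                    equilibrium_productivity, run_disturbing)

sm = generate_support_matrix(100, 0.1, np.random.default_rng(0))
lam, v = spectral_radius_and_perron(sm)          # ~10 for n=100, p_c=0.1
x_star = equilibrium_productivity(sm.C, a=100, b=1)  # totals (a/b)*lam

cfg = ScenarioConfig(society=InterSocietySpec(n_o=100, p_c_oo=0.1),
                     a_over_b=100, p_m=0.01, r_d=25, pulse_phase=20,
                     n_phases=320)
traj = run_disturbing(cfg, 7)                     # deterministic given seed
print(traj.extinct("original"), traj.totals["original"][-1])
```

## Command line — a worked example

Scenario configurations mirroring the model's standard parameter
combinations ship in `configs/`.  For example, the self-boot demonstration
with `n=100`, `p_c=0.1`, `a/b=60`, `p_m=0.01`:

```bash
evosoc boot --config configs/boot_ab60_pc0.1_pm0.01.yaml --reps 5 --out out/
evosoc analyze --out out/
```

prints

```
scenario: boot  reps: 5
extinctions(original): 0/5
original: final mean X = 624.4 (sd 15.09), mean active = 100
Shapiro-Wilk W = 0.9865 +/- 0.0040
```

Reading: all five replicates booted from a single occupation to the full 100
(`mean active = 100`, no extinctions); the final ensemble-mean total
productivity 624.4 sits at `(a/b)·λ_pf` for the realized support matrices
(`λ_pf ≈ n·p_c = 10`, so `X ≈ 60·10`, with spread from the random matrix
draws); and the per-occupation steady-state productivity profile is
bell-shaped (Shapiro–Wilk W ≈ 0.99 across replicates).  The run directory
contains `manifest.json` (provenance), `trajectory_stats.csv` (per-phase
ensemble mean/SD of totals and active counts per society) and
`summary.json` (config echo, extinction counts, normality statistics).

Every run is exactly reproducible: same config + `--seed` ⇒ byte-identical
outputs.

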