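# Methods

## The model

A society is a set of `n` potential *occupations* linked by a binary directed
*support matrix* `C`: `c_ij = 1` means occupation `j` supports occupation `i`
(raises its competitive efficiency), with self-support allowed.  Each
occupation carries a nonnegative *productivity* `x_i`, a proxy for the number
of inhabitants it feeds; `X = Σ x_i` is the society's total
productivity/population.  Two forces act on every occupation:

* **competing strength** `Cs_i = a (C x)_i` — supporting inflow from the
  occupations that support it (coefficient `a` equal for all pairs);
* **environmental restriction** `Ce = b X` — pressure from the shared
  environment, increasing linearly with total population (coefficient `b`
  equal for all occupations).

The productivity dynamics are

    dx_i/dt = a (C x)_i / x_i − b X        ("ratio" form, default)

The division by `x_i` makes the growth rate inversely proportional to the
occupation's own size, which gives small supported occupations fast relative
growth and makes the equilibria exactly the nonnegative eigenvectors of `C`.
The algebraically equivalent "product" form `dx_i/dt = a (C x)_i − b X x_i`
(same fixed points, time reparametrized) is available via
`ScenarioConfig(rate_form="product")`; the test suite checks both reach the
same fixed points.

A standalone society must be **irreducible**: its support digraph strongly
connected (every occupation supported, directly or indirectly, by every
other).  By Perron–Frobenius, an irreducible `C` then has a unique positive
eigenvector `v` (normalized to sum 1) with eigenvalue `λ_pf` = spectral
radius, and the attractor of the dynamics is

    x* = X* v,   X* = (a/b) λ_pf.

Only the ratio `a/b` matters.  For binary irreducible matrices `λ_pf ≥ 1`.
A derived (parasitic) society need not be irreducible; a reducible combined
structure still relaxes to the dominant nonnegative eigenvector with
`X* = (a/b) λ_pf` of the combined matrix.

Two further ingredients make the structure dynamic:

* **limina** — the minimum productivity an occupation needs to function
  (default 1.0, an arbitrary scale constant).  Whenever `x_i` drops below
  `limina` during a developing phase the occupation is eliminated: `x_i → 0`
  and it stops supporting others.  Eliminations cascade within one phase.
* **mutation** — at each phase boundary, every active occupation (visited in
  fresh random order) fires with probability `p_m` provided `x_i > 2·limina`;
  a firing moves exactly `limina` of productivity to a target drawn from the
  occupations currently supported by the active set (own-society targets at
  weight 1, other-society targets at weight `cross_weight`, default 0.1).
  Inactive targets are (re)created at `limina`.  Transfers conserve `X`.

Time alternates between a developing phase (relax to the attractor, with
eliminations) and a mutating phase; one develop+mutate cycle is one *phase*.

## Numerical solution of the developing phase

The default solver ("relax") is explicit Euler with a per-occupation time
step `dt_i = x_i / (b X)` and damping `w = 0.5`:

    x ← (1 − w) x + w · a (C x) / (b X)

This is a damped, normalized power iteration on `C`: its fixed points are
exactly the Perron equilibria of the active substructure, and it converges
geometrically at the power-iteration rate (the damping guarantees convergence
on periodic structures such as 2-cycles).  Elimination (`x_i < limina`) is
checked after every step and the active set reduced on the fly.  Convergence
is declared when the step change falls below `relax_rtol` (default 1e-12)
relative to the state scale; the iteration cap (1e5) is reported via a
warning if hit.  A uniform-step Euler integrator
(`method="euler"`, default `dt = 1e-3/b`, residual tolerance
`1e-8·(a/b)·b`) is provided as a time-accurate cross-check; the suite
verifies both solvers reach the same fixed points to 1e-6 relative error.
The relax solver is the default because full replicate ensembles (50 runs ×
thousands of phases × hundreds of occupations) are orders of magnitude
cheaper at identical fixed points.

The choice matters only for *transient* questions: the relax map follows a
damped interpolation to the attractor, so which occupations cross `limina`
during a violent transient (a severe disturbance pulse) can differ slightly
from the continuous-time path.  A direct comparison on matched disturbance
pulses (severity 25, 20 matrices) gave statistically indistinguishable
survivor counts for the two solvers.

Spectral quantities (`spectral_radius_and_perron`) use power iteration on
`C + I` (the unit shift makes irreducible matrices primitive and shifts every
eigenvalue by exactly +1).  On reducible input the dominant eigenvalue can be
defective and the iteration stalls at a polynomial rate; the spectral radius
then falls back to a dense eigendecomposition.

## Scenario engines

All runners are deterministic given (config, seed) and record per-phase
totals and active counts per society.

* **boot** — one self-supporting occupation at `limina` seeds the full
  society; mutation gradually creates the rest.  Demonstrates self-repair and
  the steady state `X ≈ (a/b) λ_pf` with a bell-shaped productivity profile.
* **supporting (parasitism)** — requires `p_c_do = 0`.  The original society
  `So` starts at its equilibrium; mutation populates a derived society `Sd`
  that holds productivity (and adds to the restriction) without supporting
  anyone.  At the attractor the parasite share is
  `X_d/X_o = Σ_d (C_do v_o)_d / λ_oo`, so the heavy combination
  (`n_d=200, p_c_od=0.2`) pushes mean original productivity to ≈ 2·limina and
  erodes the weakest originals.
* **disturbing** — a single pulse multiplies `b` by `r_d` for one developing
  phase.  From equilibrium, survivors scale as `x/r_d` before eliminations;
  the elimination cascade frees restriction pressure, so small dense cores
  (self-loops, reciprocal pairs) can stabilize above `limina` even when
  `r_d` exceeds the uniform-society wipeout threshold `r* = X/(n₀·limina)`.
  Survivors seed the rebuild once `b` returns to normal.
* **invading** — an intact foreign society (no cross-support, identical
  environment) enters carrying its home-equilibrium productivity profile.
  Along its own Perron profile the whole block grows or declines uniformly,
  so the contest is decided by the spectral radii and the larger-`λ_pf` block
  takes the environment.  Entry at the home equilibrium is a deliberate
  design choice: entering at `limina` per occupation instead would eliminate
  every below-average invader within the first develop instants and make
  invasion fail regardless of connectivity, contradicting the intended
  competition-by-productivity behaviour.  With equal spectral radii the
  equilibrium set is degenerate and the initial mass shares freeze: neither
  society is driven extinct.
* **mutual** — the derived society supports the original back; when the
  merged matrix is irreducible the societies fuse and the equilibrium rises
  to `(a/b) λ_pf(C_merged) > (a/b) λ_pf(C_oo)`: the growth transition.

Because the developing phase always reaches the attractor, a fully booted
society sits exactly at its Perron equilibrium at every phase boundary; the
supporting/disturbing/invading runners therefore initialise the original
society at that equilibrium directly instead of replaying the long self-boot.
This leaves every post-steady-state statistic unchanged and keeps 50-replicate
ensembles cheap.  One consequence is deliberate: the parasitized system
tracks quasi-static equilibria, whose elimination cascades are self-limiting,
so complete collapse of the original society under parasitism is rarer here
than transient-driven implementations can make it (see Limitations).

## Parameters

| name | meaning | default / typical |
| --- | --- | --- |
| `a_over_b` | supporting/restriction ratio; sets the productivity scale `X* = (a/b)λ_pf` | 60–120 |
| `n_o, n_d, n_i` | potential occupations per society | 100 / 50–200 / 100 |
| `p_c_xy` | support probability from society x to society y | 0.075–0.4 |
| `limina` | minimum functioning productivity; also the mutation quantum | 1.0 |
| `p_m` | per-occupation mutation probability per phase | 0.01–0.04 |
| `cross_weight` | relative weight of other-society mutation targets | 0.1 |
| `r_d` | pulse severity (multiplies `b` for one phase) | 4–25 |
| `n_phases` | develop+mutate cycles per run | see below |
| `n_reps` | replicates per ensemble | 50 |

Ensemble sizes and run lengths used by the shipped configurations and the
acceptance script: boot runs use 2500 phases (full occupation from a single
seed at `p_m=0.01` takes ≈ 1000–1500 phases); parasitism runs use 3000 phases
(the 200 derived occupations are fully formed and the system stationary well
before that — verified out to 10000 phases); disturbance runs use a
20-phase settling window, the pulse, and a 300-phase tail (the extinction
outcome is decided at the pulse); invasion resolves within a handful of
phases.  The directional boot comparison uses 10 replicates per parameter
combination; extinction counts use the full 50.

## What the generator emulates — and what it does not

Support structures are i.i.d. Bernoulli digraphs (block-wise between
societies), exactly the random-structure assumption of the model; for
`n=100, p_c=0.1` the first draw is almost surely irreducible and
`λ_pf ≈ n·p_c`.  Real division-of-labour networks are not Erdős–Rényi: they
have hubs, motifs, and correlated in/out degrees, and real supporting
strengths are heterogeneous where the model fixes all of them to the single
coefficient `a`.  Passing ensemble tests therefore validates the *dynamical
machinery* (equilibria, cascades, transfer bookkeeping), not any claim about
empirical societies.

## Degenerate inputs and tie-breaks

* 1×1 support matrices: `[1]` is irreducible (a self-supporting occupation is
  a legal singleton society), `[0]` is not.
* Probabilities above 1 in configs are capped to 1 with a warning.
* Mutation sources at exactly `2·limina` may not fire (strict inequality).
* Mutation target selection renormalizes weights over the eligible set;
  occupations with an empty eligible set skip their firing.
* An extinct state (no active occupation) is returned flagged, not raised,
  and passes through subsequent phases unchanged.
* Equal spectral radii in invasion: degenerate equilibria; initial mass
  shares persist and no block is eliminated.

## Known limitations

* Quasi-static developing phases (see above) under-produce collapses that
  depend on finite-rate transients, most visibly the rare complete
  elimination of a heavily parasitized society; the ensemble there reports
  erosion to ≈ 90% occupation and an ≈ 80% productivity loss instead.
* Supporting coefficients are uniform (`s_ij = a`); weighted or evolving
  coefficients, overshoot coupling, spatial structure and negative
  interactions are out of scope.
* The environmental restriction is linear in `X`; any increasing function
  preserves the qualitative behaviour but changes the norm constraint.
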