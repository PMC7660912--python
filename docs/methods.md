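# Methods

## Model overview and assumptions

The simulator couples two deterministic reaction–diffusion fields to three
stochastic agent classes on one periodic square lattice. The pro-inflammatory
mediator *c* stands in for the whole chemokine/damage axis and doubles as the
proxy for tissue damage: "resolved" means *c* and the neutrophil populations
have vanished, not that any explicit damage variable has healed. The
anti-inflammatory mediator *g* is produced only by macrophages that have
switched phenotype, and acts solely by vetoing neutrophil recruitment. Both
mediators diffuse and decay identically under the baseline parameterisation
(D = 1.5 grid²/tick, γ = 3/1440 per tick); γ_g = γ_c is a simplifying
default, overridable independently.

Space is scaled so one grid space is one macrophage diameter (20 µm) and one
tick is one minute. Cell speeds are realised by move cadence, not by a
velocity parameter: macrophages move once per tick (20 µm/min), neutrophils
twice (40 µm/min). Any number of agents may share a lattice site — the
phagocytosis rule presumes co-location — and all boundaries are periodic,
for the fields and the agents alike.

### Tick structure

Within one tick, in fixed order: (1) queued mediator deposits are added to
the lattices and both fields take their Euler substeps; (2) on ticks
divisible by 2, neutrophil recruitment sweeps the grid in uniformly shuffled
site order (recruit with probability p_nr where c > α_ncr and g < α_ngr,
until the global cap n_max); (3) on ticks divisible by 5, the macrophage
sweep does the same (p_mr where c > α_mr, cap m_max); (4) every agent acts
once, in a single uniformly shuffled order spanning all three classes, so no
class has systematic priority. A macrophage's turn runs move →
phagocytose → release → departure check → lifespan check; a removed agent
skips its later steps. A neutrophil's turn runs its two moves (each
re-reading the field and updating the remembered heading), then a possible
release, then ageing; on lifespan exhaustion it is replaced in place by an
apoptotic agent. Apoptotic agents only count down; at zero they deposit
δ_ac and vanish.

Deposits made during a tick's agent phase are applied at the *start* of the
next tick, before substepping. The ordering is a modelling choice with no
canonical answer; fixing it (and documenting it here) is what makes runs
reproducible. Deposits are per-event fixed increments (δ_ac, δ_nc, δ_mg),
not rates scaled by dt, because releases are defined as per-tick events.

### Choices where the design was genuinely open

- **Apoptotic cells and the neutrophil cap.** n_max caps *active*
  neutrophils only by default; `count_apoptotic_in_cap=True` selects the
  alternative reading of a cap on all neutrophils in the system.
- **"Absence of mediator" for the macrophage random-move fallback** is
  operationalised as max c over the 3×3 block < ε = 1e−6.
- **The departure readout** c̄ is the 3×3 sum including the macrophage's own
  site.
- **The remembered heading** is updated by every executed move, including
  apoptotic-directed and uniform-random macrophage moves, so one memory
  variable serves the whole movement model. Newly recruited cells draw a
  uniform random heading, mirroring the uniform initial distribution of the
  calibration chain.
- **Agents recruited in a tick act in that same tick**; apoptotic agents
  created mid-phase (by a death this tick) act from the next tick.
- **c0 above one is permitted** (the mediator scale is nominally [0, 1],
  fixed by δ_ac = 1): the sensitivity scan inflates c0 by 50%.

## Chemotaxis model and its calibration

The per-move distribution is the normalised product of a softmax over the
eight neighbour concentration differences (sharpness k_grad, exact
max-subtraction guards overflow) and a discretised Gaussian persistence
kernel (width σ_mem, radians) centred on the previous heading. Two
conventions were left open by the formulation and are both implemented:

- **Angular wrap.** The persistence kernel uses the circular angular
  distance (wrapped to [0, π]) by default; the raw unwrapped difference is
  selectable (`wrap_angles=False`). Unwrapped persistence is asymmetric
  around the heading (up-right and down-right become unequally reachable
  from east), contradicting the Gaussian-persistence intent, and fails to
  reproduce the tracked-cell statistics (N = 144 rather than 160).
- **Angle-to-vertical vector for the chemotactic index.** The geometric
  convention assigns 3π/4 to the downward diagonals (cosine −√2/2); the
  "symmetric-zero" variant assigns 3π/2 (cosine 0), so downward diagonals
  do not count against the index. Only the geometric convention reproduces
  the measured healthy triple (N = 160, d_v ≈ 75.4 µm, I_chem ≈ 0.39)
  jointly, so it is the default; the variant inflates the healthy index to
  ≈ 0.46.

The calibration domain is 240 × 180 grid spaces at 1 µm spacing with a
linear vertical chemoattractant profile, 0 at the bottom and 1 at the top.
The per-move vertical concentration step defaults to 1/180 (the unit drop
spread over the grid height); 1/(height − 1) is selectable and shifts the
solved move count by about one move (159 vs 160 in the healthy regime).
Every move changes the row by at most one, so straight and diagonal moves
see the same concentration step, and a single position-independent 8×8
transition matrix describes the walk. The chain computation ignores domain
boundaries; the Monte-Carlo trajectory simulator redraws boundary-crossing
moves only when `bounded=True`, which is cosmetic (for trajectory plots)
and is switched off for statistical cross-checks.

The move-count solver increments N until the expected vertical displacement
reaches velocity × duration; displacement is monotone in N under an upward
bias, and a target that is not reached within the move budget raises an
error rather than returning a spurious fit. Iso-curves of the index surface
are extracted per σ_mem by sign-change bracketing in k_grad followed by
bisection to |I_chem − target| < 1e−3; the surface is piecewise-constant in
N, so bisection also stops when the bracket collapses.

## Numerics

Explicit Euler with the five-point Laplacian is stable on a unit grid for
dt < 1/(4D); substep counts are chosen as the smallest integer n with
1/n ≤ safety/(4D), safety 0.5 by default, giving dt = 1/12 at D = 1.5.
Round-off can drive concentrations infinitesimally negative; values are
clamped to zero and counted, and a non-finite lattice raises immediately.
With D = 0 the update is exactly geometric decay, which the tests exploit
as a closed form; with γ = 0 and no sources the substeps conserve lattice
mass to round-off.

The production tick loop runs on a numba-compiled kernel (struct-of-arrays
agents, per-site CSR buckets for apoptotic co-location). The per-agent rules
also exist as plain Python functions, which are the readable reference
semantics and the `backend="python"` engine; the two backends are checked
against each other exactly on degenerate cases (no agents, probabilities
zero) and statistically on small inflamed runs, and the compiled PDE step is
checked to match the NumPy step to machine precision. Each backend is
bit-reproducible under a fixed seed; batches derive per-run seeds from one
master seed.

## Synthetic data and what the tests show

No external data is read at run time. The two motility operating points
(healthy: 3.77 µm/min and index 0.39; impaired: 0.09 µm/min and index 0.04
over a 20 min assay) are the published summary statistics of an *in-vitro*
neutrophil-tracking experiment and enter as calibration targets. The
generator of study conditions is the model itself: outcome experiments
start from a circular perturbation (c0 = 1, r = 10) with no cells and no
*g*, under the baseline constants listed in `params.py`.

The outcome experiments are run at reduced scale — 50×50 grid, 4000 ticks,
batches of 20 — where the qualitative switches are sharp: baseline →
majority chronic with the active-neutrophil count plateauing at n_max;
α_mr = 0.25 → majority resolved; α_mr = 0.25 plus impaired chemotaxis →
majority chronic again. These are properties of the reduced configuration,
chosen so a batch completes in minutes on one CPU; they demonstrate the
switching mechanisms, not quantitative agreement with any particular
tissue. The resolution classifier requires zero active and apoptotic
neutrophils *and* max c below 1e−3 at the horizon (exponential decay never
reaches zero in floating point; the tolerance sits well below every
recruitment threshold).

## Known limitations

- Long-horizon chronicity is a delicate balance between the neutrophil
  positive feedback and the anti-inflammatory blanket; on small domains the
  late-time classification can hinge on how far the mediator tail has
  decayed at the horizon rather than on a sustained cell population, and
  domain size itself shifts that balance. Conclusions should be drawn from
  batch majorities under fixed conditions, not single runs or single
  horizons.
- One-at-a-time sensitivity only; parameters likely interact, and a global
  scan is out of scope.
- No M1 pro-inflammatory macrophage feedback, no reverse phenotype
  switching, no explicit vasculature or transmigration model, and no
  explicit tissue-damage variable.
- The walk is strictly 8-direction and on-lattice; continuous-angle or
  off-lattice motility is out of scope.
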