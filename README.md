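# inflamsim

A hybrid PDE–agent-based simulator of the acute inflammatory response, for
researchers studying how spatial leukocyte behaviour decides whether a local
tissue insult resolves or becomes chronic.

Diffusible pro- and anti-inflammatory mediator fields, *c* and *g*, evolve on
a periodic lattice (one grid space = one macrophage diameter, 20 µm; one tick
= 1 min) by reaction–diffusion,

    ∂c/∂t = D_c ∇²c − γ_c c + Γ_c,
    ∂g/∂t = D_g ∇²g − γ_g g + Γ_g,

solved with a five-point Laplacian and explicit Euler substeps, where Γ_c and
Γ_g collect discrete releases by the cellular agents. Three stochastic agent
classes live on the same lattice: **active neutrophils** (recruited where
*c* > α_ncr and *g* < α_ngr, chemotax up ∇c, release *c*, and become
apoptotic when their lifespan runs out), **apoptotic neutrophils** (immobile;
necrose after a delay, dumping a unit of *c*, unless phagocytosed first), and
**macrophages** (recruited where *c* > α_mr, move preferentially onto
neighbouring apoptotic cells, phagocytose them, and after a first
phagocytosis — an M2-like phenotypic switch — release *g*, which throttles
neutrophil recruitment).

Cell movement is a biased persistent random walk over the 8-site Moore
neighbourhood: the move distribution is the normalised product of a gradient
term, p_j ∝ exp(k_grad (c_j − c_i)), and a persistence term, a discretised
Gaussian (width σ_mem) around the previous heading. On a linear
chemoattractant profile this walk is an 8-state Markov chain with transition
matrix **P**, so the expected vertical displacement after N moves,
d_v = Σ_k (Σ_{up} q_ik − Σ_{down} q_ik) with q_k = Π₀ **P**ᵏ, and the
expected mean chemotactic index, I_chem = (1/N) Σ_k Σ_i cos(α_i) q_ik, are
exactly computable. Matching d_v to a measured mean cell velocity fixes N;
matching I_chem to the measured index then calibrates (k_grad, σ_mem).
Healthy neutrophils (3.77 µm/min, index 0.39) give k_grad = 80, σ_mem = 1;
chemotactically impaired (COPD-like) neutrophils (0.09 µm/min, index 0.04)
give k_grad = 8, σ_mem = 1.2.

## Worked example

```python
import inflamsim as im

# calibrate the walk against healthy tracked-cell statistics
res = im.calibrate(velocity=3.77, duration=20.0, k_grad=80.0, sigma_mem=1.0)
print(f"N = {res.N}, d_v = {res.d_v:.2f} um, I_chem = {res.I_chem:.3f}")

# outcome experiments at reduced scale (50x50 grid, 4000 ticks)
base = im.ModelParams(grid_shape=(50, 50))
eased = base.replace(alpha_mr=0.25)   # easier macrophage recruitment
for name, p in [("baseline", base), ("alpha_mr=0.25", eased)]:
    batch = im.run_batch(p, n_reps=5, master_seed=1, T=4000)
    print(f"{name}: outcomes {batch.tally}, "
          f"peak active neutrophils {int(max(s.n_active.max() for s in batch.summaries))}")
```

prints

```
N = 160, d_v = 75.66 um, I_chem = 0.385
baseline: outcomes {'chronic': 5}, peak active neutrophils 4000
alpha_mr=0.25: outcomes {'resolved': 5}, peak active neutrophils 4000
```

A 3.77 µm/min cell must cover 75.4 µm in 20 min, which the healthy chain
achieves in 160 moves with expected chemotactic index 0.385 ≈ 0.39. In the
full model the baseline parameter set drives neutrophils to their cap and is
classified chronic at the horizon, while lowering the macrophage recruitment
threshold α_mr from 0.4 to 0.25 recruits macrophages sooner, strengthens the
anti-inflammatory feedback, and resolves the insult. Swapping in the
impaired chemotaxis pair flips that resolving set back to chronic — aberrant
neutrophil migration alone can decide the outcome.

The same operations are available from a shell:

```
inflamsim calibrate --velocity 3.77 --k-grad 80 --sigma-mem 1
inflamsim simulate --grid 50 --param alpha_mr=0.25 --ticks 4000 --seed 1 --out-dir out/
inflamsim batch --grid 50 --reps 20 --ticks 4000 --seed 1 --out-dir out/
inflamsim scan --velocity 3.77 --target-index 0.39 --out-dir out/
inflamsim sensitivity --t-eval 5000 --reps 100 --seed 1 --out-dir out/
```

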