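# evacgame

Evolutionary game model of evacuate-or-stay decisions under typhoon
warnings, simulated on small-world social networks.

When a severe typhoon approaches, residents in the danger zone must
decide whether to evacuate to safety or stay home — a decision shaped by
competition for scarce social resources (roads, shelter, emergency
supplies), by what relatives and friends decide, and by the policies a
government uses to cut evacuation costs and guarantee those who stay.
`evacgame` is a library for emergency-management researchers who want to
study how such policies shift the **evacuation response rate** — the
fraction of a population that ends up evacuating — through the diffusion
of decisions across a social network.

## The model

Two groups of residents play a 2×2 game with strategy set
{Evacuate, Stay}. With total assets *P*, abandoned fixed assets *C* (of
which *C′* is recovered through government action), evacuation-process
cost *D*, stay cost *E*, strike-probability estimate *α* and policy
coefficients *β, θ, δ, ε, η* ∈ [0, 1], the row player's cells are

    U11 = P − α(C − C′) − (1 − δ)D            both evacuate
    U12 = P − α(C − C′) − (1 − δ)(1 − β)D     evacuate vs stay
    U21 = (1 − α)P − ε(1 − θ)E                stay vs evacuate
    U22 = (1 − α)P − ηE                       both stay

*δ* is the government's evacuation-cost cut, *β* (resp. *θ*) the cost
discount created when the counterpart stays (resp. evacuates) and frees
up resources, and *ε*, *η* multiply the stay cost under partial and full
guarantee. The column player's *V* cells are the same with its own
economics.

Two dynamics are provided on top of the matrix:

* **Mean field** — replicator dynamics for the evacuating shares (x, y):
  ẋ = x(1−x)(A1·y + A2), ẏ = y(1−y)(B1·x + B2), with the affine
  advantage coefficients assembled directly from the parameters. The
  package enumerates all fixed points (the four corners plus an interior
  point (−B2/B1, −A2/A1) when it lies in the open unit square) and
  classifies each by the determinant and trace of the Jacobian
  (saddle / stable node / unstable node / center / degenerate), plus a
  fixed-step RK4 integrator for phase portraits.
* **Agent-based** — N residents on a Watts–Strogatz small-world graph
  each accumulate game payoff against their neighbours, compare with one
  randomly chosen neighbour, and — only if that neighbour did strictly
  better — imitate it with the Fermi probability
  W = 1/(1 + exp[(pr_i − pr_j)/k]), k the imitation noise. Ensembles of
  repetitions are averaged, and one-parameter policy sweeps rerun the
  ensemble along a grid with common random numbers.

## Worked example

```python
from evacgame import (GroupEconomics, PolicyParams, compute_payoff_matrix,
                      field_coefficients, find_equilibria,
                      NetworkSpec, SimConfig, run_ensemble)

econ, policy = GroupEconomics(), PolicyParams()   # reference scenario
pm = compute_payoff_matrix(econ, econ, policy)
print(pm.U11, pm.U12, pm.U21, pm.U22)             # 3.7 4.96 4.23 3.6

report = find_equilibria(field_coefficients(econ, econ, policy))
for p in report.points:
    print(f"({p.x:.3f}, {p.y:.3f})  det={p.detJ:+.3f} tr={p.trJ:+.3f}  {p.label}")

res = run_ensemble(NetworkSpec(), pm, SimConfig(n_reps=50, master_seed=1))
print(f"final evacuation response rate: {res.final_rate:.4f}")
```

prints

```
3.7 4.96 4.23 3.6
(0.000, 0.000)  det=+1.850 tr=+2.720  unstable_node
(0.000, 1.000)  det=+0.721 tr=-1.890  stable_node
(1.000, 0.000)  det=+0.721 tr=-1.890  stable_node
(1.000, 1.000)  det=+0.281 tr=+1.060  unstable_node
(0.720, 0.720)  det=-0.145 tr=+0.000  saddle
final evacuation response rate: 0.7832
```

Read: staying home is tempting exactly when others evacuate (U21 > U22),
so the mean field has five fixed points — an interior rest point at an
evacuation share of 0.72, attracting along the symmetric diagonal — and
the 200-node networked population climbs from its 50 % start to a final
response rate of 0.78, in line with that share. Each script in
`examples/` walks one capability the same way (payoff matrix, stability
report, phase portrait, ensemble simulation, policy sweep); sweeping β
over {0.05, …, 0.85}, for instance, moves the final rate monotonically
from 0.27 to 0.95.

A thin CLI mirrors the library for shell use:

```
evacgame stability                      # equilibrium report as JSON
evacgame simulate --seed 7 --out run    # run.csv + run.json
evacgame sweep --param beta --out sw    # sweep table + trend summary
```

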