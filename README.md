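# dihypernet

Simulation toolkit for **information contagion on directed social
hypernetworks**: scale-free growth models built from one-way and mutual
"follow" hyperedges, a discrete-time threshold-SEIR propagation process
driven by node intimacy, user confidence and information timeliness, its
deterministic mean-field counterpart, and an experiment harness for
parameter sweeps.

## Who this is for

Researchers in computational social science and network epidemiology who
want to study how *directional* higher-order structure — group follow
relationships where information flows from the followed to the followers
— shapes diffusion, and how it differs from undirected hypergraph or
classical pairwise SIR/SEIR dynamics.

## The model

**Substrate.** A directed hypergraph `G = (V, E)` whose hyperedges carry
disjoint tail/head node sets. In a *one-way* follow hyperedge the tail
members follow the head members and information travels head → tail; in
a *mutual* hyperedge it travels both ways. The social generator grows the
network by preferential attachment: each step `n1` new users join and
each follows `n2` existing users chosen with probability

    Π(i) ∝ ε·followers(i) + (1−ε)·followings(i) + 1,

with targets shared by several newcomers grouped into one joint
hyperedge, and each new one-way hyperedge followed back (converted to
mutual) with probability `p_mutual`. The resulting hyperdegree
distribution is heavy-tailed (scale-free).

**Propagation.** Nodes are Susceptible / Exposed / Infected / Recovered.
Per synchronous step, computed from the time-*t* snapshot:

* S → E: each infected in-neighbor *j* of a susceptible *i* transmits
  independently with probability ξ = min(ω_ij, 1), where the intimacy
  ω_ij = (n_ij + 1)^α / E[(n + 1)^α] is built from the number n_ij of
  common in-neighbors of the pair;
* E → I: deterministic threshold rule m_i(t) ≥ θ_i·K_i, where m_i counts
  infected in-neighbors, K_i = |in-neighbors| and θ_i = C(v_i) is the
  node's confidence C = 1 − e^{−w}, w ~ N(coi, σ²) truncated at 0;
  failing the threshold, the node drops out to R with probability
  η = C(v_i);
* I → R: with probability γ(t+1) = 1 − e^{−λt} — information ages, λ is
  its timeliness decay rate.

A `FIXED_RATE` mode replaces the threshold/dropout/timeliness mechanisms
with constant β, η, γ. The mean-field ODE counterpart is

    ds/dt = −s·i·ξ,   de/dt = s·i·ξ − (β+η)e,
    di/dt = βe − γi,  dr/dt = ηe + γi,

integrated with fixed-step RK4 and conserving s+e+i+r = 1.

## Worked example

```python
import numpy as np
from dihypernet import (GrowthConfig, ContagionConfig, grow_directed_social, run)

H = grow_directed_social(GrowthConfig(N=5000, n0=6, n1=2, n2=5, eps=0.8, seed=1))
print(H.n_nodes, H.n_edges, H.hyperdegrees().max())
tr = run(H, ContagionConfig(rho0=0.05, alpha=1.0, coi=0.2, lam=0.1),
         rng=np.random.default_rng(3))
print(tr.n_steps, round(tr.i.max(), 3), int(tr.i.argmax()), round(tr.r[-1], 3))
```

prints

```
5000 5259 469
16 0.533 5 1.0
```

— a 5000-user network with 5259 follow hyperedges whose most-connected
user sits in 469 of them; one outbreak seeded in 5 % of users peaks at
53 % actively-spreading users at step 5 and burns out by step 16, with
essentially every user having heard (and tired of) the information.

The same models are scriptable from the shell:

```
dihypernet generate --model social --param N=5000 --seed 1 --out net.dhl
dihypernet ensemble --net net.dhl --reps 50 --seed 1 --out curves.csv
dihypernet meanfield --xi 0.5 --beta 0.6 --eta 0.2 --gamma 0.2 --out ode.csv
dihypernet sweep --spec sweep.yaml --out sweep.csv
```

Networks are stored in a plain-text hyperedge list (`.dhl`):

```
%dihyper v1 nodes=9
0	one_way	tail:1,2,3	head:0
1	mutual	tail:1	head:4
```

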