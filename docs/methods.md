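# Methods

## Directed hypergraph substrate

A hyperedge is an ordered pair of disjoint, non-empty node sets
(tail, head). Tail members follow head members; information travels
against the follow direction, so the *in-neighbors* of a node — the
nodes that can influence it directly — are the heads of the one-way
hyperedges it sits in the tail of, plus the opposite side of every
mutual hyperedge it belongs to. A node's hyperdegree is the number of
hyperedges containing it; follower/following counts are distinct-node
quantities (a user followed through two different group edges counts
once). These two degree vocabularies coexist deliberately: hyperdegree
drives the scale-free statistics, follower/following counts drive
preferential attachment.

Incidence is stored as a pair of sparse tail/head indicator matrices;
their element-wise product is identically zero (disjointness) and every
column has at least one nonzero per side (non-emptiness). Networks
serialize to a tab-separated hyperedge list (`.dhl`) whose writer is
byte-stable, which is what makes generator determinism testable.

## Growth model

Parameters: target size `N` (default 5000), seed size `n0 = 6`, `n1 = 2`
newcomers per step, `n2 = 5` follow targets per newcomer, attachment
weight `ε = 0.8`, follow-back probability `p_mutual = 0.1`. The first
five defaults are the published experimental configuration; the
attachment kernel and `p_mutual` are this package's own choices where
the growth procedure is underdetermined:

* **Attachment kernel** Π(i) ∝ ε·followers(i) + (1−ε)·followings(i) + 1.
  The additive one keeps fresh, degree-zero users reachable; ε
  interpolates between popularity-driven (in-degree) and
  activity-driven (out-degree) attachment. Targets are sampled without
  replacement, so a newcomer follows `n2` distinct users.
* **Edge grouping.** Within a step, targets picked by two or more of the
  step's newcomers become a joint one-way hyperedge (head = the shared
  target, tail = the sharing newcomers); each newcomer's remaining
  targets form one one-way hyperedge with the newcomer as sole tail.
  This reproduces both group shapes seen in small worked examples: a
  single follower with several targets, and several followers sharing
  one target.
* **Follow-back.** Each one-way hyperedge created in a step converts to
  mutual with probability `p_mutual` in the same step; conversion flips
  the edge kind rather than adding an edge. The rate is unpublished; the
  default 0.1 keeps one-way edges dominant, as in the drawn examples.
  A consequence worth noting: a followed-back user ends up following
  more than `n2` others, so "followings = n2" holds exactly only at
  `p_mutual = 0`.
* **Seed network.** One one-way hyperedge (nodes 1..n0−2 follow node 0)
  plus one mutual hyperedge (nodes 1 and n0−1), matching the worked
  growth example at its initial stage.

Comparison substrates: a BA-style hypernetwork (one newcomer per step
joins `n2` hyperdegree-preferential targets in one mutual hyperedge), an
NW-style small-world hypernetwork (one lattice hyperedge per node over
its `K` nearest ring neighbors, plus a same-size uniformly random
shortcut hyperedge with probability `f` per lattice edge), an undirected
projection (every edge kind set to mutual), and a `rounds`-regular
random pairing network used for mean-field checks. The BA/NW models are
emitted as mutual edges because they are undirected constructions.

## Contagion model

States S, E, I, R; R is absorbing; updates are synchronous from the
time-*t* snapshot. Defaults: ρ0 = 0.05 initially infected, α = 1,
coi = 0.2, σ = 0.1, λ = 0.1 — the default configuration of the
published sweeps.

* **Transmission (S→E).** ω_ij = (n_ij+1)^α / E[(n+1)^α] over all
  propagation-adjacent ordered pairs, n_ij = common in-neighbors;
  ξ = min(ω, 1). Every infected in-neighbor of a susceptible node is an
  independent Bernoulli(ξ) trial each step; one success exposes.
* **Activation (E→I).** Deterministic on the threshold
  m_i(t) ≥ θ_i·K_i, with m counting **infected** in-neighbors only
  (exposed users are aware but silent), θ_i = C(v_i). Nodes with K = 0
  have no influence sources and never activate. Failing the threshold,
  the dropout draw fires with η = C(v_i). The threshold check precedes
  the dropout draw within a step.
* **Recovery (I→R).** γ applied at step t+1 is 1 − e^{−λt} with t the
  global step count since seeding — the decay follows the *information's*
  age, not each node's infection age, so late activations recover almost
  immediately.
* **FIXED_RATE mode** replaces activation/dropout/recovery with constant
  β, η, γ; ξ still comes from intimacy unless a constant override is
  given. Overrides for ξ, β, η, γ are honored in both modes, which makes
  degenerate limits (e.g. the pure threshold model at ξ≡1, η≡0, γ≡0)
  directly expressible.

**Randomness contract.** Each step consumes uniforms in a documented
order (active transmission pairs target-major/source-ascending, then
exposed-node draws in id order, then recovery draws in id order), so a
scripted queue of draws replays a narrative exactly and an independent
rule-by-rule oracle can be compared draw for draw. The test suite does
both.

**Pure threshold limit.** With ξ≡1, η≡0, γ≡0 and positive thresholds,
the absorbed infected set equals the monotone closure of the in-neighbor
threshold update with the initially infected as seeds. Per-step
trajectories cannot coincide with the one-stage threshold update because
the SEIR pipeline inserts a mandatory exposure step; equivalence is at
the fixed point, with each node activating no earlier than its closure
round. This is how the implementation is verified against exhaustive
enumeration.

## Mean-field ODE

ds/dt = −s·i·ξ, de/dt = s·i·ξ − (β+η)e, di/dt = βe − γi,
dr/dt = ηe + γi, all rates positive, s+e+i+r conserved. Fixed-step
classical RK4 (default dt = 0.01) — reproducibility over adaptive speed;
the right-hand side sums to zero algebraically, so conservation drift is
pure round-off (< 1e−9 over t_max = 200). The constant-γ ODE and the
time-varying agent recovery are independent surfaces; no hybrid is
attempted.

**Matching the agent model.** The ODE's scalar ξ aggregates per-contact
transmission over a node's contacts. For a constant per-contact
probability p on a K-regular network the matched coupling is
ξ = K·(−ln(1−p)); β, η, γ are hazard-converted so that both the total
probability of leaving E in one step, β + (1−β)η, and the I/R split are
preserved. A helper returning the mean capped intimacy exists for
intimacy-driven runs, but a per-contact probability near 1 (which the
normalized intimacy yields on homogeneous networks) has no useful
bilinear mean-field limit, so consistency experiments use the constant-ξ
mode. The consistency experiment itself runs N = 2000 users on a
150-regular random pairing network with p = 0.0008, β = 0.05, η = 0.016,
γ = 0.04 over 130 steps and 30 replicates: rates this small keep the
unit-step discrete process inside its continuum limit, and degree 150
keeps pair correlations negligible, which is what "dense homogeneous"
has to mean for a mean-field comparison to be a fair test.

## Statistics

* **Power-law fits** report their method. Log-log least squares over
  nonzero buckets with k ≥ k_min (default 1) gives an exponent and r²;
  the continuous maximum-likelihood (Hill) estimator uses the standard
  half-shift 1 + n/Σ ln(k/(k_min−½)) for integer data, accurate for
  k_min of a few and up. Published exponent tables for this class of
  model omit fit method and range, so no test keys on their printed
  values; tests assert heavy-tailedness (power law beating the
  exponential alternative) and seed stability instead.
* **Curve features.** Peak step is the earliest argmax of the mean
  infectious density. Steady onset is the first step from which the
  tracked densities change by less than 1e−4 for 3 consecutive steps —
  both numbers are unpublished conventions made operational here; the
  detector returns the horizon with a flag when a curve never settles.
* **Sweeps** vary one named growth or contagion parameter over an
  ensemble per value, regenerating the network each replicate and
  reusing the same per-replicate seeds across values so differences
  reflect the parameter, not the draw.

## Problem sizes used by the test suite

Full-scale experiments (N = 5000, 20–30 replicates) back the
end-to-end checks; unit and property tests run on networks of a few
hundred nodes, and oracle comparisons enumerate hypergraphs of at most
six nodes, where brute force is exact.

## Known limitations

* The agent model's reproduction of the published curve *shapes* is
  partial: the recovered-density steady onset lands where published
  (≈ step 27 at the default parameters) but the infectious peak falls at
  step 5–6 rather than 4. The reconstruction here has mean in-degree
  ≈ n2 ≈ 5, while the published model network reports a much higher mean
  in-degree (≈ 17.6) from an attachment formula whose printed form is
  truncated; denser influence neighborhoods saturate exposure faster and
  pull the peak earlier.
* Final outbreak sizes saturate near 1 at the default parameters:
  normalized intimacy has mean 1, so per-contact transmission is near
  certain and every reachable user is eventually exposed. Orderings that
  depend on sub-saturation final sizes (the ε-minimum claim, the
  undirected-projection comparison) are therefore decided by small
  margins and do not reproduce here; see the test suite for the honest
  outcomes. The undirected comparison is additionally structural: the
  projection inflates hub in-neighbor counts K, making confidence
  thresholds θ·K harder to satisfy for exactly the nodes that drive
  diffusion, which offsets the added reachability that an independently
  constructed undirected hypernetwork would provide.
* Mutual hyperedges connect tail side to head side but not nodes within
  a side, mirroring the drawn group structure; a fully cliqued reading
  of mutual groups would yield denser neighborhoods.
* No recommendation feedback, user emotion, multi-topic competition,
  competitive dual spreading, or continuous-time (Gillespie) variant.
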