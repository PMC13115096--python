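"""Discrete-time threshold-SEIR information contagion on directed hypergraphs.

States: Susceptible (unaware), Exposed (aware, not spreading), Infected
(spreading), Recovered (exited; absorbing).  Information travels against
the follow direction: an infected node can expose every node that
follows it (every node having it as an in-neighbor).

Mechanisms
----------
* **Intimacy** ω_ij = (n_ij + 1)^α / E[(n + 1)^α], where n_ij is the
  number of common in-neighbors of the ordered propagation pair j→i and
  the expectation runs over all propagation-adjacent ordered pairs.  The
  S→E transmission probability is ξ = min(ω, 1).
* **User confidence** C = 1 − exp(−w), w ~ Normal(coi, σ²) truncated at
  0.  C sets both the activation threshold fraction θ of the threshold
  rule (E→I when the number of infected in-neighbors m ≥ θ·K) and the
  E→R dropout probability η.
* **Information timeliness**: the I→R probability applied at step t+1 is
  γ = 1 − exp(−λ·t), with t the global step count since seeding.

Two modes: THRESHOLD implements the mechanisms above; FIXED_RATE uses
constant β (E→I), η (E→R) and γ (I→R) rates, with ξ still taken from
the intimacy table unless a constant ξ override is given.  Overrides are
honored in both modes, which makes limits such as ξ≡1, η≡0, γ≡0
(the pure threshold model) expressible.

Randomness contract (so scripted replays and independent oracles can
reproduce a step draw-for-draw): each synchronous step consumes
uniforms in this order —

1. one per (S target, infected in-neighbor) pair, targets ascending and
   sources ascending within a target;
2. THRESHOLD: one per E node failing its threshold, ids ascending
   (dropout draw); FIXED_RATE: one per E node ascending (β draw), then
   one per β-failing E node ascending (η draw);
3. one per I node, ids ascending (recovery draw).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .generators import (
    BAConfig,
    ConfigError,
    GrowthConfig,
    NWConfig,
    generate_ba_hypernetwork,
    generate_nw_hypernetwork,
    grow_directed_social,
)
from .hypergraph import DirectedHypergraph, HypergraphError

__all__ = [
    "State",
    "Mode",
    "ContagionConfig",
    "NodeAttributes",
    "IntimacyTable",
    "Trajectory",
    "EnsembleSummary",
    "sample_confidence",
    "intimacy",
    "transmission_prob",
    "threshold_met",
    "dropout_prob",
    "recovery_prob",
    "initialize",
    "step",
    "run",
    "run_ensemble",
    "classical_sir",
    "classical_seir",
]

S, E, I, R = 0, 1, 2, 3


class State(Enum):
    S = 0
    E = 1
    I = 2
    R = 3


class Mode(Enum):
    THRESHOLD = "threshold"
    FIXED_RATE = "fixed_rate"


@dataclass
class ContagionConfig:
    rho0: float = 0.05          # initially infected fraction
    alpha: float = 1.0          # intimacy exponent
    coi: float = 0.2            # mean of the confidence draw w
    sigma_coi: float = 0.1      # std of the confidence draw w
    lam: float = 0.1            # timeliness rate (gamma(t+1) = 1 - e^{-lam t})
    mode: Mode = Mode.THRESHOLD
    # optional constant-rate overrides; all honored in both modes
    xi: float | None = None
    beta: float | None = None
    eta: float | None = None
    gamma: float | None = None
    max_steps: int = 200
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 < self.rho0 <= 1.0:
            raise ConfigError("rho0 must lie in (0, 1]")
        if self.lam < 0:
            raise ConfigError("lam must be >= 0")
        if self.sigma_coi < 0:
            raise ConfigError("sigma_coi must be >= 0")
        for name in ("xi", "beta", "eta", "gamma"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.mode is Mode.FIXED_RATE and (self.beta is None or self.eta is None or self.gamma is None):
            raise ConfigError("FIXED_RATE mode requires beta, eta and gamma")


@dataclass
class NodeAttributes:
    """Per-node confidence draw w, confidence C = 1 - e^{-w}, and K = |in-neighbors|."""

    w: np.ndarray
    C: np.ndarray
    K: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        """Activation threshold fraction; identified with the confidence C."""
        return self.C


def sample_confidence(
    n_nodes: int, coi: float, sigma_coi: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw w ~ Normal(coi, sigma²) truncated below at 0; return (w, C)."""
    if sigma_coi < 0:
        raise ConfigError("sigma_coi must be >= 0")
    if sigma_coi == 0:
        w = np.full(n_nodes, float(coi))
    else:
        a = (0.0 - coi) / sigma_coi
        w = sps.truncnorm.rvs(a, np.inf, loc=coi, scale=sigma_coi,
                              size=n_nodes, random_state=rng)
    w = np.maximum(w, 0.0)
    return w, 1.0 - np.exp(-w)


@dataclass
class IntimacyTable:
    """Intimacy over propagation-adjacent ordered pairs, CSR by receiver.

    Row i holds the sources j in in_neighbors(i), ascending; ``n_common``
    and ``omega`` are aligned per entry.  ``normalizer`` is the mean of
    (n_common + 1)^alpha over all entries.
    """

    indptr: np.ndarray
    src: np.ndarray
    n_common: np.ndarray
    omega: np.ndarray
    normalizer: float
    alpha: float

    @property
    def n_pairs(self) -> int:
        return len(self.src)

    def lookup(self, j: int, i: int) -> float:
        """ω for the propagation pair j → i; raises if not adjacent."""
        lo, hi = self.indptr[i], self.indptr[i + 1]
        pos = lo + bisect.bisect_left(self.src[lo:hi].tolist(), j)
        if pos >= hi or self.src[pos] != j:
            raise HypergraphError(f"pair {j} -> {i} is not propagation-adjacent")
        return float(self.omega[pos])


def _in_neighbor_csr(H: DirectedHypergraph) -> tuple[np.ndarray, np.ndarray, list[set[int]]]:
    sets = H.in_neighbor_sets()
    indptr = np.zeros(H.n_nodes + 1, dtype=np.int64)
    src_rows = []
    for i, s in enumerate(sets):
        row = np.array(sorted(s), dtype=np.int64)
        src_rows.append(row)
        indptr[i + 1] = indptr[i] + len(row)
    src = np.concatenate(src_rows) if src_rows else np.zeros(0, dtype=np.int64)
    return indptr, src, sets


def intimacy(H: DirectedHypergraph, alpha: float) -> IntimacyTable:
    """Build the intimacy table ω_ij = (n_ij + 1)^α / E[(n+1)^α]."""
    indptr, src, sets = _in_neighbor_csr(H)
    if len(src) == 0:
        raise HypergraphError("no propagation-adjacent pairs; nothing can spread")
    n_common = np.empty(len(src), dtype=np.int64)
    pos = 0
    for i in range(H.n_nodes):
        si = sets[i]
        for j in src[indptr[i]:indptr[i + 1]]:
            n_common[pos] = len(si & sets[j])
            pos += 1
    raised = (n_common + 1.0) ** alpha
    normalizer = float(raised.mean())
    return IntimacyTable(indptr, src, n_common, raised / normalizer, normalizer, alpha)


def transmission_prob(j: int, i: int, table: IntimacyTable) -> float:
    """S→E probability for the pair j → i: ξ = min(ω_ij, 1)."""
    return min(table.lookup(j, i), 1.0)


def dropout_prob(C_i: float) -> float:
    """E→R probability: η = min(C, 1)."""
    return min(float(C_i), 1.0)


def recovery_prob(t: int, lam: float) -> float:
    """I→R probability applied at step t+1: γ = 1 − e^{−λ t}."""
    if lam < 0:
        raise ConfigError("lam must be >= 0")
    if t < 0:
        raise ConfigError("t must be >= 0")
    return 1.0 - float(np.exp(-lam * t))


def threshold_met(
    i: int, states: np.ndarray, attrs: NodeAttributes, in_sets: Sequence[set[int]]
) -> bool:
    """True iff the infected in-neighbor count m_i reaches θ_i · K_i.

    Nodes with no in-neighbors (K = 0) have no influence sources and
    never meet the threshold.
    """
    K = attrs.K[i]
    if K == 0:
        return False
    m = sum(1 for j in in_sets[i] if states[j] == I)
    return m >= attrs.theta[i] * K


# ---------------------------------------------------------------------------
# simulation state and stepping


@dataclass
class SimState:
    """Everything a synchronous step needs, compiled once per run."""

    H: DirectedHypergraph
    config: ContagionConfig
    states: np.ndarray            # int8, one of S/E/I/R per node
    attrs: NodeAttributes
    indptr: np.ndarray            # in-neighbor CSR by receiver
    src: np.ndarray
    tgt: np.ndarray               # receiver id per CSR entry
    xi: np.ndarray                # per-entry transmission probability
    table: IntimacyTable | None
    rng: np.random.Generator
    t: int = 0

    def counts(self) -> np.ndarray:
        return np.bincount(self.states, minlength=4)

    def densities(self) -> np.ndarray:
        return self.counts() / self.H.n_nodes


def initialize(
    H: DirectedHypergraph,
    config: ContagionConfig,
    rng: np.random.Generator | None = None,
    seeds: Sequence[int] | None = None,
    attrs: NodeAttributes | None = None,
) -> SimState:
    """Seed round(rho0·N) random infected nodes, sample confidences and
    build the intimacy table.

    ``seeds`` and ``attrs`` override the random draws for scripted
    replays (e.g. narrative fixtures).
    """
    config.validate()
    if H.n_nodes < 1:
        raise HypergraphError("empty network")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = H.n_nodes
    if seeds is None:
        k = max(1, int(round(config.rho0 * n)))
        seeds = rng.choice(n, size=k, replace=False)
    states = np.zeros(n, dtype=np.int8)
    states[np.asarray(list(seeds), dtype=np.int64)] = I

    indptr, src, sets = _in_neighbor_csr(H)
    if attrs is None:
        w, C = sample_confidence(n, config.coi, config.sigma_coi, rng)
        attrs = NodeAttributes(w=w, C=C, K=np.diff(indptr))
    elif attrs.K is None or len(attrs.K) != n:
        attrs = NodeAttributes(w=attrs.w, C=attrs.C, K=np.diff(indptr))

    table: IntimacyTable | None = None
    if config.xi is not None:
        xi = np.full(len(src), float(config.xi))
    else:
        table = intimacy(H, config.alpha)
        xi = np.minimum(table.omega, 1.0)
    tgt = np.repeat(np.arange(n, dtype=np.int64), np.diff(indptr))
    return SimState(H, config, states, attrs, indptr, src, tgt, xi, table, rng)


def step(state: SimState) -> SimState:
    """One synchronous update computed from the time-t snapshot (see the
    module docstring for the draw-order contract)."""
    cfg = state.config
    states = state.states
    n = len(states)
    rng = state.rng

    infected = states == I
    new_states = states.copy()

    # (a) transmission: S node i is exposed if any infected in-neighbor's
    # Bernoulli(xi) succeeds
    active = infected[state.src] & (states[state.tgt] == S)
    idx = np.flatnonzero(active)
    u = np.asarray(rng.random(len(idx)))
    hits = idx[u < state.xi[idx]]
    if len(hits):
        new_states[np.unique(state.tgt[hits])] = E

    # (b) exposed transitions
    e_nodes = np.flatnonzero(states == E)
    if len(e_nodes):
        m = np.bincount(state.tgt[infected[state.src]], minlength=n)
        if cfg.mode is Mode.THRESHOLD:
            K = state.attrs.K[e_nodes]
            met = (K > 0) & (m[e_nodes] >= state.attrs.theta[e_nodes] * K)
            new_states[e_nodes[met]] = I
            fail = e_nodes[~met]
            eta = (np.full(len(fail), cfg.eta) if cfg.eta is not None
                   else np.minimum(state.attrs.C[fail], 1.0))
            u2 = np.asarray(rng.random(len(fail)))
            new_states[fail[u2 < eta]] = R
        else:
            u1 = np.asarray(rng.random(len(e_nodes)))
            to_i = u1 < cfg.beta
            new_states[e_nodes[to_i]] = I
            rest = e_nodes[~to_i]
            u2 = np.asarray(rng.random(len(rest)))
            new_states[rest[u2 < cfg.eta]] = R

    # (c) infectious recovery
    i_nodes = np.flatnonzero(infected)
    if len(i_nodes):
        if cfg.gamma is not None:
            g = cfg.gamma
        elif cfg.mode is Mode.FIXED_RATE:
            raise ConfigError("FIXED_RATE mode requires gamma")
        else:
            g = recovery_prob(state.t, cfg.lam)
        u3 = np.asarray(rng.random(len(i_nodes)))
        new_states[i_nodes[u3 < g]] = R

    state.states = new_states
    state.t += 1
    return state


# ---------------------------------------------------------------------------
# trajectories and ensembles


@dataclass
class Trajectory:
    """Per-step compartment densities for one run.

    ``densities[t]`` holds (s, e, i, r) at step t, starting at t=0
    (immediately after seeding).  ``absorbed`` is False when the run hit
    max_steps with E or I still occupied.
    """

    densities: np.ndarray
    absorbed: bool
    seed: int | None = None
    states_history: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return len(self.densities) - 1

    @property
    def s(self) -> np.ndarray:
        return self.densities[:, S]

    @property
    def e(self) -> np.ndarray:
        return self.densities[:, E]

    @property
    def i(self) -> np.ndarray:
        return self.densities[:, I]

    @property
    def r(self) -> np.ndarray:
        return self.densities[:, R]


def run(
    H: DirectedHypergraph,
    config: ContagionConfig,
    rng: np.random.Generator | None = None,
    record_states: bool = False,
    seeds: Sequence[int] | None = None,
    attrs: NodeAttributes | None = None,
) -> Trajectory:
    """Run until E and I empty out or ``config.max_steps`` is reached."""
    state = initialize(H, config, rng=rng, seeds=seeds, attrs=attrs)
    dens = [state.densities()]
    hist = [state.states.copy()] if record_states else None
    absorbed = False
    while state.t < config.max_steps:
        c = state.counts()
        if c[E] == 0 and c[I] == 0:
            absorbed = True
            break
        step(state)
        dens.append(state.densities())
        if record_states:
            hist.append(state.states.copy())
    else:
        c = state.counts()
        absorbed = c[E] == 0 and c[I] == 0
    return Trajectory(
        densities=np.array(dens),
        absorbed=absorbed,
        seed=config.seed,
        states_history=np.array(hist) if record_states else None,
    )


@dataclass
class EnsembleSummary:
    """Per-step mean and std of each compartment density over replicates.

    Trajectories shorter than the longest are continued with their final
    row, which is exact once E and I have emptied (the state is then
    absorbing).
    """

    mean: np.ndarray
    std: np.ndarray
    n_reps: int
    all_absorbed: bool

    @property
    def i_mean(self) -> np.ndarray:
        return self.mean[:, I]

    @property
    def r_mean(self) -> np.ndarray:
        return self.mean[:, R]

    def sem(self) -> np.ndarray:
        return self.std / np.sqrt(self.n_reps)


NetworkSource = (
    DirectedHypergraph
    | GrowthConfig
    | BAConfig
    | NWConfig
    | Callable[[np.random.Generator], DirectedHypergraph]
)


def _realize_network(source: NetworkSource, rng: np.random.Generator) -> DirectedHypergraph:
    if isinstance(source, DirectedHypergraph):
        return source
    if isinstance(source, GrowthConfig):
        return grow_directed_social(source, rng)
    if isinstance(source, BAConfig):
        return generate_ba_hypernetwork(source, rng)
    if isinstance(source, NWConfig):
        return generate_nw_hypernetwork(source, rng)
    return source(rng)


def summarize(trajectories: Sequence[Trajectory]) -> EnsembleSummary:
    T = max(len(tr.densities) for tr in trajectories)
    padded = np.stack([
        np.vstack([tr.densities,
                   np.repeat(tr.densities[-1:], T - len(tr.densities), axis=0)])
        for tr in trajectories
    ])
    return EnsembleSummary(
        mean=padded.mean(axis=0),
        std=padded.std(axis=0, ddof=0),
        n_reps=len(trajectories),
        all_absorbed=all(tr.absorbed for tr in trajectories),
    )


def run_ensemble(
    source: NetworkSource,
    config: ContagionConfig,
    n_reps: int,
    seeds: Sequence[int] | None = None,
) -> EnsembleSummary:
    """Repeat ``run`` over replicates, regenerating the network per
    replicate when ``source`` is a generator config, and aggregate
    mean ± std per step."""
    if seeds is None:
        ss = np.random.SeedSequence(config.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
    if len(seeds) != n_reps:
        raise ConfigError("need one seed per replicate")
    trajectories = []
    for sd in seeds:
        rng = np.random.default_rng(sd)
        H = _realize_network(source, rng)
        tr = run(H, config, rng=rng)
        tr.seed = sd
        trajectories.append(tr)
    return summarize(trajectories)


# ---------------------------------------------------------------------------
# classical pairwise baselines


@dataclass
class ClassicalRates:
    """Constant rates for the classical pairwise SIR/SEIR baselines."""

    infection: float = 0.3
    recovery: float = 0.2
    incubation: float = 0.3    # E -> I (SEIR only)


def _pairwise_csr(H: DirectedHypergraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    indptr, src, _ = _in_neighbor_csr(H)
    tgt = np.repeat(np.arange(H.n_nodes, dtype=np.int64), np.diff(indptr))
    return indptr, src, tgt


def _classical(
    H: DirectedHypergraph,
    rates: ClassicalRates,
    rho0: float,
    max_steps: int,
    rng: np.random.Generator,
    latent: bool,
) -> Trajectory:
    n = H.n_nodes
    _, src, tgt = _pairwise_csr(H)
    k = max(1, int(round(rho0 * n)))
    states = np.zeros(n, dtype=np.int8)
    states[rng.choice(n, size=k, replace=False)] = I
    dens = [np.bincount(states, minlength=4) / n]
    absorbed = False
    for _ in range(max_steps):
        if not ((states == I).any() or (states == E).any()):
            absorbed = True
            break
        infected = states == I
        new_states = states.copy()
        active = np.flatnonzero(infected[src] & (states[tgt] == S))
        hits = active[rng.random(len(active)) < rates.infection]
        if len(hits):
            new_states[np.unique(tgt[hits])] = E if latent else I
        if latent:
            e_nodes = np.flatnonzero(states == E)
            go = e_nodes[rng.random(len(e_nodes)) < rates.incubation]
            new_states[go] = I
        i_nodes = np.flatnonzero(infected)
        rec = i_nodes[rng.random(len(i_nodes)) < rates.recovery]
        new_states[rec] = R
        states = new_states
        dens.append(np.bincount(states, minlength=4) / n)
    else:
        absorbed = not ((states == I).any() or (states == E).any())
    return Trajectory(densities=np.array(dens), absorbed=absorbed)


def classical_sir(
    H: DirectedHypergraph,
    rates: ClassicalRates = ClassicalRates(),
    rho0: float = 0.05,
    max_steps: int = 200,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Constant-rate SIR on the pairwise projection of ``H`` (each
    hyperedge expanded into directed source→receiver contacts)."""
    if rng is None:
        rng = np.random.default_rng()
    return _classical(H, rates, rho0, max_steps, rng, latent=False)


def classical_seir(
    H: DirectedHypergraph,
    rates: ClassicalRates = ClassicalRates(),
    rho0: float = 0.05,
    max_steps: int = 200,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Constant-rate SEIR on the pairwise projection of ``H``."""
    if rng is None:
        rng = np.random.default_rng()
    return _classical(H, rates, rho0, max_steps, rng, latent=True)
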