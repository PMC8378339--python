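"""Simulators: pure-birth fixture trees and the four trait/rate scenarios
used to validate the method.

Scenarios
---------
1. *Geometric-Brownian rates* — the model's own assumption: the log of the
   diffusion rate evolves by Brownian motion down the tree
   (:func:`simulate_rates_gbm`).
2. *Uncorrelated rates* — the same marginal rate values, shuffled uniformly
   among nodes so that phylogenetic autocorrelation is destroyed
   (:func:`permute_rates`).
3. *Discrete regime shifts* — an ordered three-state Markov (Mk) process
   paints low/medium/high rate regimes on the tree; paintings with more than
   one transition on any edge are rejected, and each surviving transition is
   relocated to its edge's midpoint (:func:`simulate_regimes_mk`).
4. *Constant rate* — plain single-rate Brownian motion
   (:func:`constant_rates`).

Trait values are then diffused along the tree with per-edge variance equal
to the edge length times the edge's (average) rate
(:func:`simulate_traits`).  Everything is bit-reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import RateState, edge_average_rate
from .phylo import Phylogeny, node_heights, parse_newick

__all__ = [
    "SimConfig",
    "MkModel",
    "RegimePainting",
    "SimulationResult",
    "simulate_pure_birth_tree",
    "simulate_rates_gbm",
    "permute_rates",
    "constant_rates",
    "simulate_regimes_mk",
    "simulate_traits",
    "simulate_scenario",
]

#: regime rates for the ordered low/medium/high discrete-shift scenario
DEFAULT_REGIME_RATES = (0.1, 1.0, 10.0)


@dataclass
class SimConfig:
    """Generating parameters shared by the simulators.

    ``sigma2_BM`` is the Brownian rate of the *log*-rates per unit time; on a
    unit-depth tree the default 1.0 spreads the node rates over several
    orders of magnitude, comparable to the rate heterogeneity the method is
    meant to detect.  ``s0``/``x0`` are the root log-rate and root trait
    state; ``seed`` makes every draw bit-reproducible.
    """

    sigma2_BM: float = 1.0
    s0: float = 0.0
    x0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_BM < 0:
            raise ValueError("sigma2_BM must be >= 0")


@dataclass
class MkModel:
    """Ordered three-state continuous-time Markov chain for rate regimes.

    States are (low, medium, high); transitions are only allowed between
    adjacent states, each at rate ``q``.  ``regime_rates`` maps each state to
    its diffusion rate sigma^2.
    """

    q: float
    regime_rates: tuple[float, float, float] = DEFAULT_REGIME_RATES
    root_state: int = 1  # start in the middle regime

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("transition rate must be >= 0")
        if self.root_state not in (0, 1, 2):
            raise ValueError("root_state must be 0, 1 or 2")

    def generator_matrix(self) -> np.ndarray:
        q = self.q
        return np.array([
            [-q, q, 0.0],
            [q, -2 * q, q],
            [0.0, q, -q],
        ])

    @classmethod
    def for_tree(cls, tree: Phylogeny, expected_shifts: float = 6.0,
                 regime_rates: tuple[float, float, float] = DEFAULT_REGIME_RATES,
                 root_state: int = 1) -> "MkModel":
        """Pick ``q`` so the expected number of transitions on the whole tree
        is about ``expected_shifts`` (the middle state leaves at rate 2q, the
        end states at q; 1.5q is used as the typical exit rate)."""
        total = float(np.nansum(tree.edge_length[1:]))
        return cls(q=expected_shifts / (1.5 * total), regime_rates=regime_rates,
                   root_state=root_state)


@dataclass
class RegimePainting:
    """Discrete regime assignment: a state per node and at most one
    midpoint-located shift per edge."""

    node_state: dict[int, int]
    shift_edges: set[int] = field(default_factory=set)  # child ids of shifted edges
    regime_rates: tuple[float, float, float] = DEFAULT_REGIME_RATES


@dataclass
class SimulationResult:
    """One simulated dataset: tree, true rates, trait values, provenance."""

    tree: Phylogeny
    rates: RateState
    traits: dict[str, float]
    painting: RegimePainting | None
    config: SimConfig
    scenario: str

    def trait_vector(self) -> np.ndarray:
        return np.array([self.traits[t] for t in self.tree.tip_labels])


def simulate_pure_birth_tree(n_tips: int, seed: int | np.random.Generator = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips, rescaled to unit depth.

    Lineages split at unit rate; after the last split the clock runs one more
    exponential waiting time so pendant edges have positive length, then all
    heights are divided by the tree depth.  Deterministic per seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # node record: [children, born_time, length]; lineages split at unit rate
    root = [[], 0.0, None]
    active = []
    for _ in range(2):
        child = [[], 0.0, None]
        root[0].append(child)
        active.append(child)
    now = 0.0
    while len(active) < n_tips:
        now += float(rng.exponential(1.0 / len(active)))
        i = int(rng.integers(len(active)))
        node = active[i]
        node[2] = now - node[1]
        daughters = [[[], now, None], [[], now, None]]
        node[0] = daughters
        active[i: i + 1] = daughters
    now += float(rng.exponential(1.0 / n_tips))
    for node in active:
        node[2] = now - node[1]

    counter = [0]

    def render(node) -> str:
        if node[0]:
            inner = ",".join(render(c) for c in node[0])
            body = f"({inner})"
        else:
            counter[0] += 1
            body = f"t{counter[0]}"
        return body if node[2] is None else f"{body}:{node[2] / now:.17g}"

    return parse_newick(render(root) + ";")


def simulate_rates_gbm(tree: Phylogeny, cfg: SimConfig) -> RateState:
    """Log-rates evolving by Brownian motion down the tree (geometric
    Brownian motion of the rates themselves).

    The root log-rate is ``cfg.s0``; each child adds an independent
    ``Normal(0, sigma2_BM * edge_length)`` increment to its parent's value.
    """
    rng = np.random.default_rng(cfg.seed)
    snode = np.empty(tree.n_nodes + 1)
    snode[tree.root_id] = cfg.s0
    for v in tree.preorder():
        if v == tree.root_id:
            continue
        sd = np.sqrt(cfg.sigma2_BM * tree.edge_length[v])
        snode[v] = snode[tree.parent[v]] + rng.normal(0.0, sd)
    s = np.array([snode[v] for v in tree.ext_node_ids()])
    return RateState(s, cfg.s0)


def permute_rates(rates: RateState, seed: int | np.random.Generator = 0) -> RateState:
    """Shuffle the non-root log-rates uniformly among nodes.

    Preserves the multiset of rate values exactly (and the root log-rate)
    while destroying their phylogenetic autocorrelation — the second
    validation scenario.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = rates.s.copy()
    rng.shuffle(s)
    return RateState(s, rates.s0)


def constant_rates(tree: Phylogeny, sigma2: float = 1.0) -> RateState:
    """Every node at the same rate (plain single-rate Brownian motion)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    return RateState.constant(tree, float(np.log(sigma2)))


def simulate_regimes_mk(
    tree: Phylogeny,
    model: MkModel,
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> tuple[RegimePainting, RateState]:
    """Paint ordered rate regimes on the tree under the Mk chain.

    States evolve along each edge with exponential waiting times from the
    generator matrix.  Whole paintings in which any edge carries two or more
    transitions are rejected and redrawn; each surviving transition is then
    relocated to its edge's midpoint, so every edge has at most one shift and
    node states are well defined.  Node log-rates are the log of the regime
    rate at each node.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = model.generator_matrix()
    out_rate = -np.diag(Q)

    for _ in range(max_tries):
        node_state: dict[int, int] = {tree.root_id: model.root_state}
        shift_edges: set[int] = set()
        ok = True
        for v in tree.preorder():
            if v == tree.root_id:
                continue
            state = node_state[tree.parent[v]]
            length = tree.edge_length[v]
            t = 0.0
            transitions = 0
            while True:
                r = out_rate[state]
                if r == 0:
                    break
                t += float(rng.exponential(1.0 / r))
                if t >= length:
                    break
                probs = Q[state].copy()
                probs[state] = 0.0
                state = int(rng.choice(3, p=probs / probs.sum()))
                transitions += 1
            if transitions > 1:
                ok = False
                break
            node_state[v] = state
            if transitions == 1:
                shift_edges.add(v)
        if ok:
            painting = RegimePainting(node_state=node_state, shift_edges=shift_edges,
                                      regime_rates=model.regime_rates)
            log_r = np.log(np.asarray(model.regime_rates))
            s = np.array([log_r[node_state[v]] for v in tree.ext_node_ids()])
            return painting, RateState(s, float(log_r[model.root_state]))
    raise RuntimeError(
        f"no painting without multi-shift edges in {max_tries} tries; "
        "use smaller transition rates"
    )


def simulate_traits(
    tree: Phylogeny,
    rates: RateState,
    cfg: SimConfig,
    painting: RegimePainting | None = None,
) -> dict[str, float]:
    """Diffuse the trait from the root along every edge.

    Each child's value is its parent's plus ``Normal(0, r * t)`` where ``t``
    is the edge length and ``r`` the edge's average rate: the logarithmic
    mean of the endpoint rates in the continuous scenarios, or — under a
    regime painting — the regime rate itself (arithmetically averaged across
    a midpoint shift, which is exact for a shift at the midpoint).
    """
    rng = np.random.default_rng(cfg.seed)
    snode = rates.node_log_rates(tree)
    xnode = np.empty(tree.n_nodes + 1)
    xnode[tree.root_id] = cfg.x0
    for v in tree.preorder():
        if v == tree.root_id:
            continue
        p = tree.parent[v]
        if painting is not None:
            rp = painting.regime_rates[painting.node_state[p]]
            rc = painting.regime_rates[painting.node_state[v]]
            r = 0.5 * (rp + rc) if v in painting.shift_edges else rc
        else:
            r = edge_average_rate(snode[p], snode[v])
        xnode[v] = xnode[p] + rng.normal(0.0, np.sqrt(r * tree.edge_length[v]))
    return {lab: float(xnode[i + 1]) for i, lab in enumerate(tree.tip_labels)}


def simulate_scenario(
    scenario: str,
    n_tips: int = 50,
    seed: int = 0,
    cfg: SimConfig | None = None,
    expected_shifts: float = 6.0,
    constant_sigma2: float = 1.0,
) -> SimulationResult:
    """One-call driver for the four validation scenarios.

    ``scenario`` is one of ``"gbm"``, ``"uncorrelated"``, ``"mk"``,
    ``"constant"``.  Sub-seeds for the tree, the rates and the traits are
    derived deterministically from ``seed``.
    """
    if scenario not in ("gbm", "uncorrelated", "mk", "constant"):
        raise ValueError(f"unknown scenario {scenario!r}")
    base = cfg or SimConfig(seed=seed)
    ss = np.random.SeedSequence(base.seed)
    seed_tree, seed_rates, seed_traits, seed_extra = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    tree = simulate_pure_birth_tree(n_tips, seed_tree)
    painting = None
    if scenario == "gbm":
        rates = simulate_rates_gbm(tree, SimConfig(base.sigma2_BM, base.s0, base.x0, seed_rates))
    elif scenario == "uncorrelated":
        rates = simulate_rates_gbm(tree, SimConfig(base.sigma2_BM, base.s0, base.x0, seed_rates))
        rates = permute_rates(rates, seed_extra)
    elif scenario == "mk":
        model = MkModel.for_tree(tree, expected_shifts=expected_shifts)
        painting, rates = simulate_regimes_mk(tree, model, seed_rates)
    else:
        rates = constant_rates(tree, constant_sigma2)
    traits = simulate_traits(
        tree, rates, SimConfig(base.sigma2_BM, base.s0, base.x0, seed_traits), painting
    )
    return SimulationResult(tree=tree, rates=rates, traits=traits,
                            painting=painting, config=base, scenario=scenario)
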