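"""Ground-truth reaction networks and simulated steady-state metabolite samples.

This module provides the generative side of the benchmark: a sparse,
kinetically parameterized reaction network (the ground truth), steady-state
concentration samples obtained by perturbing kinetic parameters and
integrating the mass-balance ODEs, and "condition shifts" that emulate a
biological state change by scaling the Michaelis-Menten parameters of
selected reactions.

Rate laws
---------
mass_action        v = k * prod(substrate concentrations)
michaelis_menten   v = Vmax * prod_s S/(Km + S)

Each reaction consumes every substrate and produces every product at rate v.
Efflux (removal) reactions are first-order mass-action sinks attached to the
terminal metabolites of the network; they keep the system from accumulating
mass indefinitely and are excluded from the interaction adjacency.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

NETWORK_FORMAT_VERSION = "1"

# generator parameter ranges (log-uniform), in concentration/hour units.
# Constraints that make every generated system reach a strictly positive
# steady state within the 90 h horizon: the total influx (<= K_IN max) is
# below every reaction's capacity (k, Vmax minima), so no metabolite
# accumulates without bound, and every first-order relaxation rate
# (k, Vmax/Km, k_out) is >= 0.2 / h, so transients decay by many e-folds
# before the hard stop.
K_RANGE = (0.5, 5.0)
VMAX_RANGE = (1.0, 5.0)
KM_RANGE = (0.5, 5.0)
K_OUT_RANGE = (0.2, 0.5)
K_IN_RANGE = (0.05, 0.2)

# steady-state criterion: max_i |dC_i/dt| / max(C_i, eps) < tol
STEADY_STATE_TOL = 1e-6
STEADY_STATE_EPS = 1e-12
NEGATIVE_CLIP = 1e-9

MASS_ACTION = "mass_action"
MICHAELIS_MENTEN = "michaelis_menten"


class SimulationError(RuntimeError):
    """Integration failed or produced invalid concentrations."""


class FormatError(ValueError):
    """A file did not conform to the documented CSV/JSON dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One reaction with its kinetic law and parameters.

    ``efflux`` marks first-order removal reactions; these are the only
    reactions allowed an empty product list (their product is the implicit
    sink outside the system).  ``influx`` marks constant-rate supply
    reactions (empty substrate list; with mass-action law the empty product
    over substrates makes the rate the constant k).
    """

    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    law: str
    params: dict[str, float]
    efflux: bool = False
    influx: bool = False

    def __post_init__(self) -> None:
        if self.law not in (MASS_ACTION, MICHAELIS_MENTEN):
            raise ValueError(f"unknown rate law {self.law!r}")
        if self.efflux and self.influx:
            raise ValueError(f"reaction {self.id}: cannot be both influx and efflux")
        if not self.substrates and not self.influx:
            raise ValueError(f"reaction {self.id}: empty substrate list (not influx)")
        if not self.products and not self.efflux:
            raise ValueError(f"reaction {self.id}: empty product list (not efflux)")
        for name, value in self.params.items():
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"reaction {self.id}: parameter {name}={value} must be positive")
        required = {MASS_ACTION: {"k"}, MICHAELIS_MENTEN: {"Vmax", "Km"}}[self.law]
        if set(self.params) != required:
            raise ValueError(f"reaction {self.id}: law {self.law} needs params {sorted(required)}")

    @property
    def participants(self) -> tuple[str, ...]:
        return self.substrates + self.products


@dataclass(frozen=True)
class MetabolicNetwork:
    """Metabolite nodes plus kinetically parameterized reactions.

    ``core`` names the designated central metabolite (used as the high
    initial-concentration species in simulations); defaults to the first node.
    """

    nodes: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    core: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        known = set(self.nodes)
        for r in self.reactions:
            missing = set(r.participants) - known
            if missing:
                raise ValueError(f"reaction {r.id} references unknown nodes {sorted(missing)}")
        if self.core is not None and self.core not in known:
            raise ValueError(f"core metabolite {self.core!r} not a node")

    @property
    def efflux_nodes(self) -> frozenset[str]:
        return frozenset(s for r in self.reactions if r.efflux for s in r.substrates)

    def internal_reactions(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if not r.efflux and not r.influx)

    def validate(self, require_efflux: bool = True) -> None:
        """Check connectivity and (optionally) efflux at every terminal node."""
        adj = network_to_adjacency(self)
        n = len(self.nodes)
        if n > 1:
            # connectivity of the undirected projection via BFS
            seen = {0}
            stack = [0]
            neighbors = [np.flatnonzero(adj.values[i]) for i in range(n)]
            while stack:
                i = stack.pop()
                for j in neighbors[i]:
                    if j not in seen:
                        seen.add(int(j))
                        stack.append(int(j))
            if len(seen) != n:
                raise ValueError("undirected projection is not connected")
        if require_efflux:
            degree = adj.values.sum(axis=0)
            terminals = {self.nodes[i] for i in np.flatnonzero(degree == 1)}
            missing = terminals - self.efflux_nodes
            if missing:
                raise ValueError(f"terminal nodes without efflux: {sorted(missing)}")

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "format_version": NETWORK_FORMAT_VERSION,
            "nodes": list(self.nodes),
            "core": self.core,
            "reactions": [
                {
                    "id": r.id,
                    "substrates": list(r.substrates),
                    "products": list(r.products),
                    "law": r.law,
                    "params": r.params,
                    "efflux": r.efflux,
                    "influx": r.influx,
                }
                for r in self.reactions
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MetabolicNetwork":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format_version") != NETWORK_FORMAT_VERSION:
            raise FormatError(f"unsupported network format_version {payload.get('format_version')!r}")
        reactions = tuple(
            Reaction(
                id=r["id"],
                substrates=tuple(r["substrates"]),
                products=tuple(r["products"]),
                law=r["law"],
                params={k: float(v) for k, v in r["params"].items()},
                efflux=bool(r.get("efflux", False)),
                influx=bool(r.get("influx", False)),
            )
            for r in payload["reactions"]
        )
        return cls(nodes=tuple(payload["nodes"]), reactions=reactions, core=payload.get("core"))


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary symmetric reference matrix over named metabolites."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError(f"adjacency shape {v.shape} does not match {n} names")
        if not np.array_equal(v, v.T):
            raise FormatError("adjacency matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise FormatError("adjacency diagonal must be zero")
        if not np.isin(v, (0, 1)).all():
            raise FormatError("adjacency entries must be 0/1")
        object.__setattr__(self, "values", v.astype(np.int8))

    @property
    def n_edges(self) -> int:
        return int(self.values.sum() // 2)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.names), columns=list(self.names)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "AdjacencyMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise FormatError("adjacency row and column names differ")
        return cls(names=tuple(df.columns), values=df.to_numpy())


@dataclass(frozen=True)
class SampleMatrix:
    """Samples (rows) by metabolites (columns), nonnegative concentrations."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.names):
            raise ValueError(f"sample matrix shape {v.shape} does not match {len(self.names)} names")
        if not np.isfinite(v).all():
            raise FormatError("sample matrix contains non-finite entries")
        if (v < 0).any():
            raise FormatError("sample matrix contains negative concentrations")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, rows: np.ndarray) -> "SampleMatrix":
        return SampleMatrix(self.names, self.values[np.asarray(rows)])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.names))
        df.insert(0, "sample_id", [f"s{i}" for i in range(len(df))])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleMatrix":
        df = pd.read_csv(path)
        if df.columns[0] == "sample_id":
            df = df.drop(columns="sample_id")
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise FormatError(f"NaN concentrations in columns {bad}")
        return cls(names=tuple(df.columns), values=df.to_numpy(dtype=float))


@dataclass(frozen=True)
class ConditionShift:
    """Multiplicative shifts of Vmax/Km for selected Michaelis-Menten reactions."""

    targets: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for rid, vmax_mult, km_mult in self.targets:
            if not (vmax_mult > 0 and km_mult > 0):
                raise ValueError(f"shift for {rid}: multipliers must be strictly positive")


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_network(
    n_nodes: int,
    n_extra_edges: int = 0,
    mm_fraction: float = 0.5,
    seed: int = 0,
) -> MetabolicNetwork:
    """Generate a sparse, connected, kinetically parameterized reaction network.

    A random spanning tree over ``n_nodes`` metabolites is built by attaching
    each new node to a uniformly chosen earlier one, then ``n_extra_edges``
    additional substrate->product reactions are added between non-adjacent
    pairs (creating cycles).  All reactions are oriented away from the root
    "core" metabolite (node 0).  Each internal reaction is Michaelis-Menten
    with probability ``mm_fraction``, mass-action otherwise; parameters are
    drawn log-uniformly.  Every terminal (degree-1) node receives a
    first-order efflux reaction, and the core metabolite a constant-rate
    influx so the open system settles to a strictly positive steady state.
    Deterministic for a fixed seed.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if not 0 <= mm_fraction <= 1:
        raise ValueError("mm_fraction must lie in [0, 1]")
    max_extra = n_nodes * (n_nodes - 1) // 2 - (n_nodes - 1)
    if not 0 <= n_extra_edges <= max_extra:
        raise ValueError(f"n_extra_edges must lie in [0, {max_extra}] for {n_nodes} nodes")

    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_nodes - 1)))
    nodes = tuple(f"M{i:0{width}d}" for i in range(n_nodes))

    # spanning tree, oriented away from the root; record depth for orientation
    depth = {0: 0}
    edges: list[tuple[int, int]] = []  # (substrate index, product index)
    for child in range(1, n_nodes):
        parent = int(rng.integers(0, child))
        edges.append((parent, child))
        depth[child] = depth[parent] + 1

    present = {frozenset(e) for e in edges}
    candidates = [
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if frozenset((i, j)) not in present
    ]
    if n_extra_edges:
        pick = rng.choice(len(candidates), size=n_extra_edges, replace=False)
        for idx in sorted(int(p) for p in pick):
            i, j = candidates[idx]
            # orient away from the root: shallower node is the substrate
            if (depth[j], j) < (depth[i], i):
                i, j = j, i
            edges.append((i, j))

    reactions: list[Reaction] = []
    for ridx, (i, j) in enumerate(edges):
        if rng.random() < mm_fraction:
            law = MICHAELIS_MENTEN
            params = {
                "Vmax": float(_loguniform(rng, *VMAX_RANGE)),
                "Km": float(_loguniform(rng, *KM_RANGE)),
            }
        else:
            law = MASS_ACTION
            params = {"k": float(_loguniform(rng, *K_RANGE))}
        reactions.append(
            Reaction(
                id=f"r{ridx:03d}",
                substrates=(nodes[i],),
                products=(nodes[j],),
                law=law,
                params=params,
            )
        )

    # efflux at every terminal (degree-1) node and at every directed sink
    # (no outgoing reaction); without removal at the sinks these
    # end-of-pathway metabolites accumulate without bound and no steady
    # state exists
    degree = np.zeros(n_nodes, dtype=int)
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    has_outgoing = {i for i, _ in edges}
    targets = sorted(set(np.flatnonzero(degree == 1)) | (set(range(n_nodes)) - has_outgoing))
    for t in targets:
        reactions.append(
            Reaction(
                id=f"efflux_{nodes[t]}",
                substrates=(nodes[int(t)],),
                products=(),
                law=MASS_ACTION,
                params={"k": float(_loguniform(rng, *K_OUT_RANGE))},
                efflux=True,
            )
        )
    reactions.append(
        Reaction(
            id=f"influx_{nodes[0]}",
            substrates=(),
            products=(nodes[0],),
            law=MASS_ACTION,
            params={"k": float(_loguniform(rng, *K_IN_RANGE))},
            influx=True,
        )
    )

    net = MetabolicNetwork(nodes=nodes, reactions=tuple(reactions), core=nodes[0])
    net.validate()
    return net


def network_to_adjacency(net: MetabolicNetwork) -> AdjacencyMatrix:
    """Binary interaction matrix: 1 iff some non-efflux reaction links the pair.

    A multi-substrate reaction induces edges among *all* its participants
    (substrate-substrate as well as substrate-product), the inclusive reading
    of "reaction partners share an edge".
    """
    index = {name: i for i, name in enumerate(net.nodes)}
    n = len(net.nodes)
    adj = np.zeros((n, n), dtype=np.int8)
    for r in net.internal_reactions():
        members = sorted({index[p] for p in r.participants})
        for a_pos, a in enumerate(members):
            for b in members[a_pos + 1 :]:
                adj[a, b] = adj[b, a] = 1
    return AdjacencyMatrix(names=net.nodes, values=adj)


# ---------------------------------------------------------------------------
# steady-state simulation
# ---------------------------------------------------------------------------


def _compile_rates(net: MetabolicNetwork):
    """Precompute index arrays so the RHS avoids name lookups."""
    index = {name: i for i, name in enumerate(net.nodes)}
    compiled = []
    for r in net.reactions:
        sub = np.array([index[s] for s in r.substrates], dtype=np.intp)
        prod = np.array([index[p] for p in r.products], dtype=np.intp)
        compiled.append((sub, prod, r.law, dict(r.params)))
    return compiled


def _rhs_factory(compiled, param_scale: np.ndarray):
    """Mass-balance derivative with per-reaction parameter multipliers.

    ``param_scale`` has one row per reaction: column 0 scales k or Vmax,
    column 1 scales Km (unused for mass action).
    """

    def rhs(_t: float, c: np.ndarray) -> np.ndarray:
        cpos = np.maximum(c, 0.0)
        dc = np.zeros_like(c)
        for ridx, (sub, prod, law, params) in enumerate(compiled):
            if law == MASS_ACTION:
                v = params["k"] * param_scale[ridx, 0] * np.prod(cpos[sub])
            else:
                km = params["Km"] * param_scale[ridx, 1]
                s = cpos[sub]
                v = params["Vmax"] * param_scale[ridx, 0] * np.prod(s / (km + s))
            np.subtract.at(dc, sub, v)
            np.add.at(dc, prod, v)
        return dc

    return rhs


def initial_concentrations(net: MetabolicNetwork, baseline: float = 1.0, core_value: float = 10.0) -> np.ndarray:
    x0 = np.full(len(net.nodes), baseline, dtype=float)
    core = net.core or net.nodes[0]
    x0[net.nodes.index(core)] = core_value
    return x0


def _integrate_to_steady_state(rhs, x0: np.ndarray, t_end: float, sample_index: int,
                               n_checks: int = 6) -> np.ndarray:
    """Integrate with a stiff solver, stopping early once derivatives vanish.

    The steady-state criterion max_i |dC_i/dt| / max(C_i, eps) < tol is
    checked at each of ``n_checks`` intermediate times after a burn-in of the
    first segment; integration hard-stops at ``t_end``.
    """
    bounds = np.linspace(0.0, t_end, n_checks + 1)
    state = np.asarray(x0, dtype=float)
    for seg in range(n_checks):
        sol = solve_ivp(
            rhs, (bounds[seg], bounds[seg + 1]), state,
            method="LSODA", rtol=1e-8, atol=1e-12,
        )
        if not sol.success:
            raise SimulationError(f"sample {sample_index}: integration failed ({sol.message})")
        state = sol.y[:, -1]
        negative = state < 0
        if negative.any():
            if np.min(state) < -NEGATIVE_CLIP:
                raise SimulationError(
                    f"sample {sample_index}: concentration {np.min(state):.3e} below tolerance"
                )
            state = np.where(negative, 0.0, state)
        if seg >= 1:  # burn-in: never stop inside the first segment
            deriv = rhs(bounds[seg + 1], state)
            rel = np.abs(deriv) / np.maximum(state, STEADY_STATE_EPS)
            if np.max(rel) < STEADY_STATE_TOL:
                break
    return state


def simulate_samples(
    net: MetabolicNetwork,
    n_samples: int,
    perturb: float = 0.10,
    t_end: float = 90.0,
    seed: int = 0,
    x0: np.ndarray | None = None,
    return_residuals: bool = False,
) -> SampleMatrix | tuple[SampleMatrix, np.ndarray]:
    """Steady-state concentration samples under kinetic parameter perturbation.

    For each sample every kinetic parameter is independently multiplied by a
    uniform draw from [1-perturb, 1+perturb], the mass-balance ODEs are
    integrated from fixed initial concentrations (all 1.0, the core metabolite
    at 10.0 unless ``x0`` overrides) until ``t_end`` simulated hours or until
    the steady-state criterion is met, and the final concentration vector
    becomes one row.  Deterministic for a fixed seed.

    With ``return_residuals`` the per-sample steady-state residual
    max_i |dC_i/dt| / max(C_i, eps), re-evaluated with that sample's
    realized (perturbed) parameters, is returned alongside the samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if perturb < 0:
        raise ValueError("perturb must be >= 0")
    compiled = _compile_rates(net)
    base_x0 = initial_concentrations(net) if x0 is None else np.asarray(x0, dtype=float)
    rng = np.random.default_rng(seed)
    rows = np.empty((n_samples, len(net.nodes)), dtype=float)
    residuals = np.empty(n_samples)
    n_reactions = len(net.reactions)
    for s in range(n_samples):
        scale = rng.uniform(1.0 - perturb, 1.0 + perturb, size=(n_reactions, 2))
        rhs = _rhs_factory(compiled, scale)
        rows[s] = _integrate_to_steady_state(rhs, base_x0, t_end, s)
        deriv = rhs(t_end, rows[s])
        residuals[s] = float(np.max(np.abs(deriv) / np.maximum(rows[s], STEADY_STATE_EPS)))
    samples = SampleMatrix(names=net.nodes, values=rows)
    return (samples, residuals) if return_residuals else samples


def rate_derivatives(net: MetabolicNetwork, concentrations: np.ndarray) -> np.ndarray:
    """Evaluate dC/dt at a given state with unperturbed parameters."""
    compiled = _compile_rates(net)
    scale = np.ones((len(net.reactions), 2))
    return _rhs_factory(compiled, scale)(0.0, np.asarray(concentrations, dtype=float))


# ---------------------------------------------------------------------------
# condition shifts
# ---------------------------------------------------------------------------


def apply_condition(net: MetabolicNetwork, shift: ConditionShift) -> MetabolicNetwork:
    """Return a copy of the network with Vmax/Km of targeted reactions scaled."""
    by_id = {r.id: r for r in net.reactions}
    for rid, _, _ in shift.targets:
        if rid not in by_id:
            raise ValueError(f"shift targets unknown reaction {rid!r}")
        if by_id[rid].law != MICHAELIS_MENTEN:
            raise ValueError(f"shift targets non-Michaelis-Menten reaction {rid!r}")
    mults = {rid: (vm, km) for rid, vm, km in shift.targets}
    reactions = tuple(
        replace(
            r,
            params={"Vmax": r.params["Vmax"] * mults[r.id][0], "Km": r.params["Km"] * mults[r.id][1]},
        )
        if r.id in mults
        else r
        for r in net.reactions
    )
    return replace(net, reactions=reactions)


# ---------------------------------------------------------------------------
# reference file loading
# ---------------------------------------------------------------------------


def load_reference(adjacency_path, samples_path) -> tuple[AdjacencyMatrix, SampleMatrix]:
    """Load a deposited adjacency CSV and samples CSV, aligning column order."""
    adj = AdjacencyMatrix.from_csv(adjacency_path)
    samples = SampleMatrix.from_csv(samples_path)
    if set(samples.names) != set(adj.names):
        missing = set(adj.names) ^ set(samples.names)
        raise FormatError(f"metabolite name sets differ between files: {sorted(missing)[:5]}...")
    if samples.names != adj.names:
        logger.info("reordering sample columns to match adjacency name order")
        order = [samples.names.index(n) for n in adj.names]
        samples = SampleMatrix(names=adj.names, values=samples.values[:, order])
    return adj, samples
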