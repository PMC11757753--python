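"""Hill-function gene-regulatory network models.

This is the mechanistic counterpart of the random-Jacobian ensembles: small
signed network topologies whose node dynamics follow

    dx_i/dt = b_i + V_i * prod(activating Hill factors)
                  * prod(repressing Hill factors)  - mu_i * x_i,

with activating factor 1 / (1 + (K/x_j)^n) and repressing factor
1 / (1 + (x_j/K)^n); independent (non-competitive) regulators combine
multiplicatively.  Parameter sets are drawn by Latin-hypercube sampling in
log space, steady states are located by a damped Newton iteration from
several random starting points, and the analytic Jacobian at each steady
state feeds the dispersion classifier.  Screening many parameter sets
yields the empirical distributions of Jacobian elements conditioned on the
instability class — the data that motivates modelling Jacobians as random
matrices in the first place.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .dispersion import CLASS_NAMES, KGrid, classify_batch
from .ensembles import DiffusionSpec, substream

__all__ = [
    "Topology",
    "HillParams",
    "HillParamsBatch",
    "SteadyStateSet",
    "DEFAULT_BOUNDS",
    "example_topology",
    "load_topology",
    "save_topology",
    "rhs",
    "jacobian",
    "find_steady_states",
    "lhs_sample",
    "screen_models",
]

#: log-uniform sampling bounds for the kinetic parameters (arbitrary units)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "V": (0.1, 10.0),
    "K": (0.01, 1.0),
    "b": (0.001, 0.1),
    "mu": (0.01, 1.0),
}

#: Hill coefficient used throughout unless overridden
DEFAULT_HILL_N = 2.0


@dataclasses.dataclass(frozen=True)
class Topology:
    """Signed regulatory topology.

    ``adjacency[i, j]`` is the sign of the edge j -> i: +1 activation,
    -1 inhibition, 0 absent.  Self-edges are permitted.  The two diffusing
    species are by convention nodes 1 and 2 (indices 0 and 1).
    """

    adjacency: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=int)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(adj, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be in {-1, 0, +1}")
        object.__setattr__(self, "adjacency", adj)
        if not self.names:
            object.__setattr__(
                self, "names", tuple(f"node{i+1}" for i in range(adj.shape[0]))
            )
        elif len(self.names) != adj.shape[0]:
            raise ValueError("names length must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    @property
    def edge_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) arrays of regulated node / regulator for each edge."""
        return np.nonzero(self.adjacency)


def save_topology(topology: Topology, path) -> None:
    doc = {
        "names": list(topology.names),
        "adjacency": topology.adjacency.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_topology(path) -> Topology:
    doc = yaml.safe_load(Path(path).read_text())
    return Topology(np.asarray(doc["adjacency"]), tuple(doc.get("names", ())))


def example_topology(n_nodes: int) -> Topology:
    """Documented example topologies with 2-4 nodes.

    * 2 nodes: a Gierer-Meinhardt-type activator-inhibitor pair — node 1
      activates itself and node 2; node 2 inhibits node 1 and itself.
    * 3 nodes: the same core extended with an immobile node 3 in a negative
      feedback loop (1 activates 3, 3 inhibits 1).
    * 4 nodes: additionally node 2 activates an immobile node 4 which
      inhibits node 2.
    """
    if n_nodes == 2:
        adj = [[1, -1], [1, -1]]
    elif n_nodes == 3:
        adj = [[1, -1, -1], [1, -1, 0], [1, 0, 0]]
    elif n_nodes == 4:
        adj = [[1, -1, -1, 0], [1, -1, 0, -1], [1, 0, 0, 0], [0, 1, 0, 0]]
    else:
        raise ValueError("example topologies exist for 2, 3 or 4 nodes")
    return Topology(np.asarray(adj))


@dataclasses.dataclass(frozen=True)
class HillParams:
    """Kinetic parameters of one Hill-function model.

    ``b``, ``V``, ``mu`` are per-node positive rates; ``K`` and ``n`` are
    (N, N) arrays defined wherever the topology has an edge (entries on
    absent edges are ignored).
    """

    b: np.ndarray
    V: np.ndarray
    mu: np.ndarray
    K: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        for name in ("b", "V", "mu", "K", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.b > 0).all() or not (self.V > 0).all() or not (self.mu > 0).all():
            raise ValueError("b, V, mu must be strictly positive")


class HillParamsBatch:
    """Stack of parameter sets: arrays with a leading sample axis.

    Behaves as a sequence of :class:`HillParams`.
    """

    def __init__(self, b, V, mu, K, n):
        self.b = np.asarray(b, dtype=float)
        self.V = np.asarray(V, dtype=float)
        self.mu = np.asarray(mu, dtype=float)
        self.K = np.asarray(K, dtype=float)
        self.n = np.asarray(n, dtype=float)

    def __len__(self) -> int:
        return self.b.shape[0]

    def __getitem__(self, idx) -> HillParams:
        if isinstance(idx, (int, np.integer)):
            return HillParams(self.b[idx], self.V[idx], self.mu[idx],
                              self.K[idx], self.n[idx])
        return HillParamsBatch(self.b[idx], self.V[idx], self.mu[idx],
                               self.K[idx], self.n[idx])


@dataclasses.dataclass
class SteadyStateSet:
    """Distinct positive steady states found for one parameter set."""

    states: list[np.ndarray]
    n_converged: int
    n_guesses: int
    residuals: list[float]

    def __len__(self) -> int:
        return len(self.states)


def _factors(adj, K, n, X):
    """Hill factors for every (target i, regulator j): shape (..., N, N).

    Entries on absent edges are 1 so that products over regulators are
    unaffected.  With t = (x_j / K_ij)^n, activation is t/(1+t) and
    repression 1/(1+t).
    """
    xj = X[..., None, :]
    with np.errstate(over="ignore"):
        t = (xj / K) ** n
    act = t / (1.0 + t)
    rep = 1.0 / (1.0 + t)
    fac = np.where(adj > 0, act, np.where(adj < 0, rep, 1.0))
    return fac, t


def _regulated(adj) -> np.ndarray:
    """Boolean per-node mask: node has at least one regulator.

    A node with no incoming edges is produced at its basal rate only; the
    maximal-rate term exists only together with its regulating Hill factors.
    """
    return np.asarray(adj != 0).any(axis=-1)


def _rhs_core(adj, b, V, mu, K, n, X):
    fac, _ = _factors(adj, K, n, X)
    prod = fac.prod(axis=-1)
    return b + V * prod * _regulated(adj) - mu * X


def _jacobian_core(adj, b, V, mu, K, n, X):
    fac, t = _factors(adj, K, n, X)
    prod = fac.prod(axis=-1)
    # d(log factor)/dx_j: activation n/(x (1+t)); repression -n t/(x (1+t))
    xj = X[..., None, :]
    dlog = np.where(
        adj > 0,
        n / (xj * (1.0 + t)),
        np.where(adj < 0, -n * t / (xj * (1.0 + t)), 0.0),
    )
    J = V[..., None] * prod[..., None] * dlog
    J = np.where(adj != 0, J, 0.0)
    nn = X.shape[-1]
    idx = np.arange(nn)
    J[..., idx, idx] -= mu
    return J


def _check_positive(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    return x


def rhs(topology: Topology, params: HillParams, x: np.ndarray) -> np.ndarray:
    """Time derivative f(x) of the Hill model at concentrations x (> 0)."""
    x = _check_positive(x)
    return _rhs_core(topology.adjacency, params.b, params.V, params.mu,
                     params.K, params.n, x)


def jacobian(topology: Topology, params: HillParams, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian J_ij = d f_i / d x_j of the Hill model at x (> 0)."""
    x = _check_positive(x)
    return _jacobian_core(topology.adjacency, params.b, params.V, params.mu,
                          params.K, params.n, x)


def _newton_batch(adj, b, V, mu, K, n, X0, tol=1e-9, max_iter=100):
    """Damped Newton iteration on a batch of starting points.

    Steps are shortened so iterates stay strictly positive.  Returns the
    final iterates, their residuals and a convergence mask.
    """
    X = X0.copy()
    B, nn = X.shape
    b = np.broadcast_to(b, (B, nn))
    V = np.broadcast_to(V, (B, nn))
    mu = np.broadcast_to(mu, (B, nn))
    K = np.broadcast_to(K, (B, nn, nn))
    n = np.broadcast_to(n, (B, nn, nn))
    alive = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        F = _rhs_core(adj, b, V, mu, K, n, X)
        res = np.abs(F).max(axis=-1)
        alive = np.isfinite(res) & (res >= tol)
        if not alive.any():
            break
        J = _jacobian_core(adj, b[alive], V[alive], mu[alive], K[alive],
                           n[alive], X[alive])
        Fa = F[alive]
        try:
            dx = np.linalg.solve(J, -Fa[..., None])[..., 0]
        except np.linalg.LinAlgError:
            J = J + 1e-10 * np.eye(J.shape[-1])
            try:
                dx = np.linalg.solve(J, -Fa[..., None])[..., 0]
            except np.linalg.LinAlgError:
                break
        Xa = X[alive]
        # largest step fraction keeping every coordinate positive
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(dx < 0, -0.9 * Xa / dx, np.inf).min(axis=-1)
        alpha = np.minimum(1.0, frac)
        Xa = Xa + alpha[:, None] * dx
        bad = ~np.isfinite(Xa).all(axis=-1) | (Xa <= 0).any(axis=-1)
        Xa[bad] = np.nan
        X[alive] = Xa
    F = np.where(
        np.isfinite(X).all(axis=-1, keepdims=True) & (X > 0).all(axis=-1, keepdims=True),
        _rhs_core(adj, b, V, mu, K, n, np.where(np.isfinite(X) & (X > 0), X, 1.0)),
        np.inf,
    )
    res = np.abs(F).max(axis=-1)
    converged = np.isfinite(res) & (res < tol)
    return X, res, converged


def _dedup(roots: np.ndarray, rel_tol: float = 1e-4) -> np.ndarray:
    """Indices of unique roots under a relative L-infinity metric."""
    keep: list[int] = []
    for i, r in enumerate(roots):
        dup = False
        for j in keep:
            scale = np.maximum(np.abs(roots[j]), np.abs(r))
            scale = np.where(scale > 0, scale, 1.0)
            if np.max(np.abs(roots[j] - r) / scale) < rel_tol:
                dup = True
                break
        if not dup:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def find_steady_states(
    topology: Topology,
    params: HillParams,
    n_guesses: int = 10,
    seed: int = 0,
    tol: float = 1e-9,
    guess_range: tuple[float, float] = (1e-3, 1e2),
) -> SteadyStateSet:
    """Locate positive steady states f(x*) = 0 by multi-start Newton.

    Starting points are log-uniform in ``guess_range`` per coordinate;
    converged roots are filtered to strictly positive vectors and
    de-duplicated (relative L-infinity distance < 1e-4).  An empty set is a
    legitimate outcome, not an error.
    """
    rng = substream(seed, "newton")
    nn = topology.n_nodes
    lo, hi = np.log(guess_range[0]), np.log(guess_range[1])
    X0 = np.exp(rng.uniform(lo, hi, size=(n_guesses, nn)))
    X, res, conv = _newton_batch(
        topology.adjacency, params.b, params.V, params.mu, params.K, params.n,
        X0, tol=tol,
    )
    roots = X[conv]
    resids = res[conv]
    if len(roots):
        keep = _dedup(roots)
        roots, resids = roots[keep], resids[keep]
    return SteadyStateSet(
        states=[r.copy() for r in roots],
        n_converged=int(conv.sum()),
        n_guesses=n_guesses,
        residuals=[float(r) for r in resids],
    )


def lhs_sample(
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    topology: Topology | None = None,
    hill_n: float = DEFAULT_HILL_N,
) -> HillParamsBatch:
    """Latin-hypercube sample of kinetic parameter sets, log-uniform marginals.

    Each of the model's free parameters (V_i, b_i, mu_i per node and K_ij
    per edge) is stratified into ``n_samples`` equal-probability bins in log
    space with exactly one draw per bin.  Hill coefficients are fixed at
    ``hill_n`` (default 2).
    """
    if topology is None:
        topology = example_topology(2)
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    for key, (lo, hi) in bounds.items():
        if not (0 < lo < hi):
            raise ValueError(f"invalid bounds for {key}: ({lo}, {hi})")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    nn = topology.n_nodes
    ei, ej = topology.edge_indices
    n_edges = len(ei)
    dim = 3 * nn + n_edges
    sampler = qmc.LatinHypercube(d=dim, seed=substream(seed, "lhs"))
    u = sampler.random(n=n_samples)

    def scale(u_block, lo, hi):
        return np.exp(np.log(lo) + u_block * (np.log(hi) - np.log(lo)))

    V = scale(u[:, 0:nn], *bounds["V"])
    b = scale(u[:, nn : 2 * nn], *bounds["b"])
    mu = scale(u[:, 2 * nn : 3 * nn], *bounds["mu"])
    k_edges = scale(u[:, 3 * nn :], *bounds["K"])
    K = np.ones((n_samples, nn, nn))
    K[:, ei, ej] = k_edges
    n = np.full((n_samples, nn, nn), float(hill_n))
    return HillParamsBatch(b, V, mu, K, n)


def _steady_states_batch(topology, batch, n_guesses, seed, tol=1e-9,
                         guess_range=(1e-3, 1e2), chunk=200_000):
    """All distinct steady states for every parameter set in a batch.

    Returns (set_ids, states) with states shaped (n_states, N).
    """
    S = len(batch)
    nn = topology.n_nodes
    rng = substream(seed, "screen-guesses")
    lo, hi = np.log(guess_range[0]), np.log(guess_range[1])
    X0 = np.exp(rng.uniform(lo, hi, size=(S, n_guesses, nn)))

    adj = topology.adjacency
    set_ids: list[np.ndarray] = []
    states: list[np.ndarray] = []
    per_chunk = max(1, chunk // n_guesses)
    for s0 in range(0, S, per_chunk):
        sl = slice(s0, min(S, s0 + per_chunk))
        ns = sl.stop - sl.start
        rep = lambda a: np.repeat(a[sl], n_guesses, axis=0)
        X, res, conv = _newton_batch(
            adj, rep(batch.b), rep(batch.V), rep(batch.mu),
            rep(batch.K), rep(batch.n),
            X0[sl].reshape(ns * n_guesses, nn), tol=tol,
        )
        X = X.reshape(ns, n_guesses, nn)
        conv = conv.reshape(ns, n_guesses)
        # vectorised per-set dedup over at most n_guesses roots
        scale = np.maximum(np.abs(X[:, :, None, :]), np.abs(X[:, None, :, :]))
        scale = np.where(scale > 0, scale, 1.0)
        with np.errstate(invalid="ignore"):
            close = (np.abs(X[:, :, None, :] - X[:, None, :, :]) / scale).max(-1) < 1e-4
        close &= conv[:, :, None] & conv[:, None, :]
        earlier = np.tril(np.ones((n_guesses, n_guesses), dtype=bool), k=-1)
        unique = conv & ~np.any(close & earlier[None], axis=1)
        sid, gid = np.nonzero(unique)
        set_ids.append(sid + sl.start)
        states.append(X[sid, gid])
    return np.concatenate(set_ids), np.concatenate(states) if states else np.empty((0, nn))


def screen_models(
    topology: Topology,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_samples: int = 1000,
    diff: DiffusionSpec = DiffusionSpec(),
    k_grid: KGrid = KGrid(),
    seed: int = 0,
    n_guesses: int = 10,
    out_path=None,
) -> pd.DataFrame:
    """Screen LHS parameter sets for Turing instabilities; emit element records.

    For every parameter set and every one of its steady states, the
    analytic Jacobian is evaluated and classified; one record is emitted per
    structurally nonzero Jacobian element (edges plus the always-present
    degradation diagonal) with columns
    ``set_id, state_id, i, j, value, klass``.  Multistable sets contribute
    one block of records per steady state.  If ``out_path`` is given the
    records are also streamed to CSV.
    """
    if n_samples == 0:
        df = pd.DataFrame(columns=["set_id", "state_id", "i", "j", "value", "klass"])
        if out_path is not None:
            df.to_csv(out_path, index=False)
        return df
    batch = lhs_sample(bounds, n_samples, seed, topology)
    set_ids, states = _steady_states_batch(topology, batch, n_guesses, seed)
    nn = topology.n_nodes
    if len(set_ids) == 0:
        df = pd.DataFrame(columns=["set_id", "state_id", "i", "j", "value", "klass"])
        if out_path is not None:
            df.to_csv(out_path, index=False)
        return df

    sub = batch[set_ids]
    jacs = _jacobian_core(topology.adjacency, sub.b, sub.V, sub.mu, sub.K,
                          sub.n, states)
    codes, flagged = classify_batch(jacs, diff, k_grid)

    # state index within each set (sets are contiguous in set_ids)
    state_id = np.zeros(len(set_ids), dtype=int)
    same = np.r_[False, set_ids[1:] == set_ids[:-1]]
    run = 0
    for idx in range(1, len(set_ids)):  # cumulative count within runs
        run = run + 1 if same[idx] else 0
        state_id[idx] = run

    mask = np.asarray(topology.adjacency != 0)
    np.fill_diagonal(mask, True)  # degradation makes the diagonal structural
    ii, jj = np.nonzero(mask)
    n_el = len(ii)

    keep = ~flagged
    rec = pd.DataFrame(
        {
            "set_id": np.repeat(set_ids[keep], n_el),
            "state_id": np.repeat(state_id[keep], n_el),
            "i": np.tile(ii, keep.sum()),
            "j": np.tile(jj, keep.sum()),
            "value": jacs[keep][:, ii, jj].ravel(),
            "klass": np.repeat(
                np.array(CLASS_NAMES, dtype=object)[codes[keep]], n_el
            ),
        }
    )
    if out_path is not None:
        rec.to_csv(out_path, index=False)
    return rec
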