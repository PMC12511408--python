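"""Gaussian Bayesian-network structure learning and bootstrap consensus.

Structures are learned by greedy hill climbing over DAGs, maximizing the
decomposable Gaussian BIC score

    score(G) = sum_i [ loglik(x_i | parents_i) - (|parents_i| + 2)/2 ln n ]

with loglik the profile Gaussian log-likelihood, -n/2 (ln(2 pi s2_i) + 1),
where s2_i is the residual variance of node i regressed on its parents.
Moves are single edge additions, deletions and reversals; the best
score-improving acyclic move is applied until a local optimum.  All local
scores are computed from the empirical covariance matrix by Schur
complements, which makes the climb fast enough for bootstrap ensembles.

The consensus step resamples rows with replacement, learns one structure
per resample, and retains edges whose (direction-blind) frequency reaches
the retention threshold, orienting each by its majority direction.  Taxa
are then classified as directly or indirectly associated with SCFAs by
graph adjacency/connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

_EPS = 1e-12
_MIN_VAR = 1e-12


def _standardize(data: np.ndarray, names: list[str]) -> np.ndarray:
    sd = data.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = [names[j] for j in np.where(sd <= 0)[0]]
        raise DomainError(f"constant column(s): {bad}")
    return (data - data.mean(axis=0)) / sd


class _HillClimber:
    """Cached greedy hill climb on one dataset.

    Caches, per node y, the score delta of adding each candidate parent x
    and of deleting each current parent; reversal deltas are composed from
    the two.  After a move only the touched node(s) are recomputed.
    """

    def __init__(self, data: np.ndarray, names: list[str], max_parents: int | None = None):
        self.n, self.d = data.shape
        if self.n < 5:
            raise DomainError("need >= 5 samples to learn a structure")
        self.names = names
        self.max_parents = max_parents
        X = _standardize(data, names)
        S = (X.T @ X) / (self.n - 1)
        self.S = (S + S.T) / 2.0
        self.parents: list[list[int]] = [[] for _ in range(self.d)]
        self.adj = np.zeros((self.d, self.d), dtype=bool)  # adj[x, y]: x -> y
        self.logn = np.log(self.n)
        self.add_delta = np.full((self.d, self.d), -np.inf)  # [x, y]
        self.del_delta = np.full((self.d, self.d), -np.inf)  # [x, y]
        self._resvar = np.ones(self.d)
        for y in range(self.d):
            self._refresh(y)

    # -- local scores -----------------------------------------------------
    def _cond_var(self, y: int, pa: list[int]) -> float:
        if not pa:
            return float(self.S[y, y])
        Spp = self.S[np.ix_(pa, pa)]
        Spy = self.S[pa, y]
        sol = np.linalg.solve(Spp, Spy)
        return float(self.S[y, y] - Spy @ sol)

    def _score_from_var(self, var: float, k: int) -> float:
        var = max(var, _MIN_VAR)
        loglik = -0.5 * self.n * (np.log(2 * np.pi * var) + 1.0)
        return loglik - 0.5 * (k + 2) * self.logn

    def _refresh(self, y: int) -> None:
        """Recompute cached add/delete deltas for node y."""
        pa = self.parents[y]
        var_y = self._cond_var(y, pa)
        self._resvar[y] = var_y
        base = self._score_from_var(var_y, len(pa))
        # Additions, vectorized over all candidates x.
        Syy = self.S[:, y].copy()
        if pa:
            Spp = np.linalg.inv(self.S[np.ix_(pa, pa)])
            Sp_all = self.S[np.ix_(pa, range(self.d))]  # |pa| x d
            cond_xy = Syy - Sp_all.T @ (Spp @ self.S[pa, y])
            cond_xx = np.diag(self.S) - np.einsum(
                "ij,jk,ki->i", Sp_all.T, Spp, Sp_all
            )
        else:
            cond_xy = Syy
            cond_xx = np.diag(self.S).copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            var_new = var_y - np.where(cond_xx > _EPS, cond_xy**2 / cond_xx, 0.0)
        var_new = np.clip(var_new, _MIN_VAR, None)
        add = (
            -0.5 * self.n * (np.log(2 * np.pi * var_new) + 1.0)
            - 0.5 * (len(pa) + 3) * self.logn
        ) - base
        add[y] = -np.inf
        add[pa] = -np.inf
        if self.max_parents is not None and len(pa) >= self.max_parents:
            add[:] = -np.inf
        self.add_delta[:, y] = add
        # Deletions.
        self.del_delta[:, y] = -np.inf
        for x in pa:
            rest = [q for q in pa if q != x]
            var_rest = self._cond_var(y, rest)
            self.del_delta[x, y] = (
                self._score_from_var(var_rest, len(rest)) - base
            )

    # -- graph utilities --------------------------------------------------
    def _has_path(self, src: int, dst: int) -> bool:
        """Directed path src ~> dst (DFS on the current adjacency)."""
        if src == dst:
            return True
        stack = [src]
        seen = np.zeros(self.d, dtype=bool)
        seen[src] = True
        while stack:
            v = stack.pop()
            nxt = np.where(self.adj[v] & ~seen)[0]
            if dst in nxt:
                return True
            seen[nxt] = True
            stack.extend(nxt.tolist())
        return False

    # -- main loop --------------------------------------------------------
    def run(self, max_iter: int = 10_000) -> nx.DiGraph:
        for _ in range(max_iter):
            move = self._best_move()
            if move is None:
                break
            self._apply(move)
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for x, y in zip(*np.where(self.adj)):
            g.add_edge(self.names[x], self.names[y])
        return g

    def _best_move(self):
        # Candidate matrices in fixed operation order (add < delete <
        # reverse); np.argmax takes the first maximum, which realizes the
        # lexicographic (operation, source, target) tie-break.
        rev = np.full((self.d, self.d), -np.inf)
        xs, ys = np.where(self.adj)
        rev[xs, ys] = self.del_delta[xs, ys] + self.add_delta[ys, xs]
        add = np.where(self.adj | self.adj.T, -np.inf, self.add_delta)
        stack = np.stack([add, self.del_delta, rev])
        flat = stack.reshape(3, -1)
        order_ok = flat > 1e-10
        while order_ok.any():
            idx = int(np.argmax(np.where(order_ok, flat, -np.inf)))
            op, rest = divmod(idx, self.d * self.d)
            x, y = divmod(rest, self.d)
            if stack[op, x, y] <= 1e-10:
                return None
            if op == 0:  # add x -> y: forbidden if path y ~> x exists
                if not self._has_path(y, x):
                    return ("add", x, y, stack[op, x, y])
            elif op == 1:
                return ("delete", x, y, stack[op, x, y])
            else:  # reverse x -> y: need no other path x ~> y
                self.adj[x, y] = False
                cyclic = self._has_path(x, y)
                self.adj[x, y] = True
                if not cyclic:
                    return ("reverse", x, y, stack[op, x, y])
            order_ok[op, x * self.d + y] = False
            flat[op, x * self.d + y] = -np.inf
        return None

    def _apply(self, move) -> None:
        op, x, y, _ = move
        if op == "add":
            self.adj[x, y] = True
            self.parents[y].append(x)
            self.parents[y].sort()
            self._refresh(y)
        elif op == "delete":
            self.adj[x, y] = False
            self.parents[y].remove(x)
            self._refresh(y)
        else:
            self.adj[x, y] = False
            self.adj[y, x] = True
            self.parents[y].remove(x)
            self.parents[x].append(y)
            self.parents[x].sort()
            self._refresh(y)
            self._refresh(x)


def learn_structure(
    data: pd.DataFrame, seed: int = 0, *, max_parents: int | None = None
) -> nx.DiGraph:
    """Greedy hill-climbing Gaussian-BIC structure learning.

    ``data`` is a sample-by-variable numeric DataFrame (it is standardized
    internally).  The climb starts from the empty graph and is
    deterministic given the data; ``seed`` is accepted for interface
    symmetry and reserved for optional random restarts.
    """
    names = [str(c) for c in data.columns]
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DomainError("missing values in network data; exclude them first")
    return _HillClimber(X, names, max_parents=max_parents).run()


@dataclass
class ConsensusNetwork:
    nodes: list[str]
    edge_freq: dict[tuple[str, str], float]  # directed frequencies
    retained_edges: pd.DataFrame  # source, target, frequency, undirected flag, sign
    n_boot: int
    retention: float
    seed: int

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, row in self.retained_edges.iterrows():
            g.add_edge(
                row["source"],
                row["target"],
                frequency=row["frequency"],
                sign=row["sign"],
                undirected=bool(row["undirected"]),
            )
        return g

    def to_frame(self) -> pd.DataFrame:
        return self.retained_edges.copy()


def _partial_corr_sign(S: np.ndarray, i: int, j: int) -> int:
    """Sign of the partial correlation of (i, j) given all other variables
    (from the precision matrix); annotation only, never a filter."""
    prec = np.linalg.pinv(S)
    return int(np.sign(-prec[i, j]))


def bootstrap_consensus(
    data: pd.DataFrame,
    n_boot: int = 500,
    retention: float = 0.5,
    seed: int = 0,
    *,
    max_parents: int | None = None,
) -> ConsensusNetwork:
    """Bootstrap ensemble of learned structures and its consensus graph.

    Undirected edge frequency = fraction of bootstraps containing the edge
    in either direction; edges with frequency >= ``retention`` are kept and
    oriented by majority direction (exact ties flagged undirected, stored
    in lexicographic order).  Any directed cycle among retained edges is
    broken by dropping the cycle's lowest-frequency edge.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    names = [str(c) for c in data.columns]
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DomainError("missing values in network data; exclude them first")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    dir_counts: dict[tuple[str, str], int] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = X[idx]
        # Guard against degenerate resamples of near-constant columns.
        if (sample.std(axis=0) <= 0).any():
            idx = rng.integers(0, n, size=n)
            sample = X[idx]
        g = _HillClimber(sample, names, max_parents=max_parents).run()
        for e in g.edges:
            dir_counts[e] = dir_counts.get(e, 0) + 1

    edge_freq = {e: cnt / n_boot for e, cnt in dir_counts.items()}
    undirected: dict[tuple[str, str], float] = {}
    for (a, b), f in edge_freq.items():
        key = (a, b) if a <= b else (b, a)
        undirected[key] = undirected.get(key, 0.0) + f

    Sfull = np.cov(_standardize(X, names), rowvar=False)
    name_ix = {nm: i for i, nm in enumerate(names)}
    rows = []
    for (a, b), f in sorted(undirected.items(), key=lambda kv: (-kv[1], kv[0])):
        if f < retention:
            continue
        fab = edge_freq.get((a, b), 0.0)
        fba = edge_freq.get((b, a), 0.0)
        if fab > fba:
            src, dst, tie = a, b, False
        elif fba > fab:
            src, dst, tie = b, a, False
        else:
            src, dst, tie = a, b, True  # tie: flagged undirected
        rows.append(
            {
                "source": src,
                "target": dst,
                "frequency": min(f, 1.0),
                "undirected": tie,
                "sign": _partial_corr_sign(Sfull, name_ix[src], name_ix[dst]),
            }
        )
    retained = pd.DataFrame(
        rows, columns=["source", "target", "frequency", "undirected", "sign"]
    )

    # Break directed cycles by dropping the weakest edge of each cycle.
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for _, row in retained.iterrows():
        if not row["undirected"]:
            g.add_edge(row["source"], row["target"], frequency=row["frequency"])
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: g.edges[e[0], e[1]]["frequency"])
        g.remove_edge(weakest[0], weakest[1])
        retained = retained[
            ~(
                (retained["source"] == weakest[0])
                & (retained["target"] == weakest[1])
                & (~retained["undirected"])
            )
        ].reset_index(drop=True)

    return ConsensusNetwork(
        nodes=names,
        edge_freq=edge_freq,
        retained_edges=retained,
        n_boot=n_boot,
        retention=retention,
        seed=seed,
    )


def scfa_neighborhood(
    net: ConsensusNetwork, scfa_ids: list[str]
) -> pd.DataFrame:
    """Classify every non-SCFA node as a direct, indirect, or unconnected
    SCFA associate (direction-blind connectivity on retained edges).

    ``via_transit_only`` marks nodes whose every connecting path runs
    through the transit node.
    """
    missing = [s for s in scfa_ids if s not in net.nodes]
    if missing:
        raise KeyError(f"unknown node(s) {missing}")
    g = net.graph().to_undirected()
    scfa_set = set(scfa_ids)
    g_no_transit = g.copy()
    if "transit" in g_no_transit:
        g_no_transit.remove_node("transit")
    rows = []
    for node in net.nodes:
        if node in scfa_set:
            continue
        direct = any(g.has_edge(node, s) for s in scfa_ids)
        connected = any(
            s in g and node in g and nx.has_path(g, node, s) for s in scfa_ids
        )
        if direct:
            cat = "direct"
        elif connected:
            cat = "indirect"
        else:
            cat = "none"
        via_transit_only = False
        if cat != "none" and node != "transit" and "transit" in g:
            via_transit_only = not any(
                s in g_no_transit
                and node in g_no_transit
                and nx.has_path(g_no_transit, node, s)
                for s in scfa_ids
            )
        rows.append({"node": node, "category": cat, "via_transit_only": via_transit_only})
    return pd.DataFrame(rows, columns=["node", "category", "via_transit_only"])
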