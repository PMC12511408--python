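import networkx as nx
import numpy as np
import pandas as pd
import pytest

import scfa_micromap as sm
from scfa_micromap.errors import ConfigError, DomainError


def chain_data(seed, n=500, noise=0.3):
    """A -> B -> C linear-Gaussian chain with unit slopes."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=n)
    B = A + noise * rng.normal(size=n)
    C = B + noise * rng.normal(size=n)
    return pd.DataFrame({"A": A, "B": B, "C": C})


def skeleton(g) -> set:
    return {tuple(sorted(e)) for e in g.edges}


class TestLearnStructure:
    def test_chain_skeleton_recovered(self):
        hits = sum(
            skeleton(sm.learn_structure(chain_data(seed))) == {("A", "B"), ("B", "C")}
            for seed in range(25)
        )
        assert hits / 25 >= 0.95

    def test_independent_columns_give_empty_graph(self):
        empty = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            data = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("WXYZ"))
            empty += sm.learn_structure(data).number_of_edges() == 0
        assert empty / 25 >= 0.9

    def test_duplicate_column_yields_single_edge_fixed_by_tiebreak(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        data = pd.DataFrame({"u": x, "v": x.copy()})
        g1 = sm.learn_structure(data)
        g2 = sm.learn_structure(data)
        assert g1.number_of_edges() == 1
        assert list(g1.edges) == list(g2.edges)  # deterministic direction

    def test_constant_column_named_in_error(self):
        data = pd.DataFrame({"a": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(DomainError, match="flat"):
            sm.learn_structure(data)

    def test_result_is_acyclic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 6))
        X[:, 1] += X[:, 0]
        X[:, 2] += X[:, 1]
        X[:, 3] += 0.5 * X[:, 0]
        g = sm.learn_structure(pd.DataFrame(X, columns=list("abcdef")))
        assert nx.is_directed_acyclic_graph(g)

    def test_max_parents_cap_respected(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 6))
        X[:, 5] = X[:, :5].sum(axis=1) + 0.1 * rng.normal(size=300)
        g = sm.learn_structure(pd.DataFrame(X, columns=list("abcdef")), max_parents=2)
        assert max(g.in_degree(n) for n in g.nodes) <= 2


class TestBootstrapConsensus:
    def test_chain_consensus_and_no_shortcut_edge(self):
        net = sm.bootstrap_consensus(chain_data(7), n_boot=50, seed=1)
        skel = {tuple(sorted((r.source, r.target))) for r in net.retained_edges.itertuples()}
        assert skel == {("A", "B"), ("B", "C")}
        assert net.retained_edges.frequency.min() > 0.9

    def test_pure_noise_retains_nothing(self):
        # Same dimensionality as the chain system (3 variables, n = 500).
        none = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            data = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
            net = sm.bootstrap_consensus(data, n_boot=30, seed=seed)
            none += net.retained_edges.shape[0] == 0
        assert none / 20 >= 0.9

    def test_single_bootstrap_degenerates_to_one_graph(self):
        data = chain_data(11, n=200)
        net = sm.bootstrap_consensus(data, n_boot=1, seed=4)
        assert set(net.edge_freq.values()) <= {1.0}
        rng = np.random.default_rng(4)
        idx = rng.integers(0, 200, 200)
        g = sm.learn_structure(data.iloc[idx])
        assert {tuple(sorted(e)) for e in g.edges} == {
            tuple(sorted((r.source, r.target))) for r in net.retained_edges.itertuples()
        }

    def test_retained_set_shrinks_as_retention_rises(self):
        data = chain_data(13, n=150, noise=0.8)
        nets = [
            sm.bootstrap_consensus(data, n_boot=40, retention=r, seed=9)
            for r in (0.3, 0.5, 0.8)
        ]
        sets = [
            {tuple(sorted((e.source, e.target))) for e in n.retained_edges.itertuples()}
            for n in nets
        ]
        assert sets[2] <= sets[1] <= sets[0]

    def test_frequencies_within_unit_interval_and_zero_nboot_rejected(self):
        net = sm.bootstrap_consensus(chain_data(5, n=100), n_boot=10, seed=0)
        assert all(0.0 <= f <= 1.0 for f in net.edge_freq.values())
        with pytest.raises(ConfigError):
            sm.bootstrap_consensus(chain_data(5, n=100), n_boot=0)

    def test_retained_graph_is_acyclic(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(150, 5))
        X[:, 1] += X[:, 0]
        X[:, 2] += X[:, 1] + 0.5 * X[:, 0]
        net = sm.bootstrap_consensus(pd.DataFrame(X, columns=list("abcde")), n_boot=30, seed=2)
        g = net.graph()
        directed = nx.DiGraph(
            [(r.source, r.target) for r in net.retained_edges.itertuples() if not r.undirected]
        )
        assert nx.is_directed_acyclic_graph(directed)


class TestScfaNeighborhood:
    def make_net(self, edges):
        nodes = sorted({n for e in edges for n in e[:2]} | {"acetate", "transit", "T9"})
        rows = [
            {"source": a, "target": b, "frequency": f, "undirected": False, "sign": 1}
            for a, b, f in edges
        ]
        return sm.ConsensusNetwork(
            nodes=nodes,
            edge_freq={(a, b): f for a, b, f in edges},
            retained_edges=pd.DataFrame(
                rows, columns=["source", "target", "frequency", "undirected", "sign"]
            ),
            n_boot=10,
            retention=0.5,
            seed=0,
        )

    def test_direct_indirect_and_none(self):
        net = self.make_net([("T1", "T2", 0.9), ("T2", "acetate", 0.8)])
        cats = sm.scfa_neighborhood(net, ["acetate"]).set_index("node")["category"]
        assert cats["T2"] == "direct"
        assert cats["T1"] == "indirect"
        assert cats["T9"] == "none"

    def test_empty_retained_set_gives_all_none(self):
        net = self.make_net([])
        cats = sm.scfa_neighborhood(net, ["acetate"])["category"]
        assert set(cats) == {"none"}

    def test_transit_mediated_paths_flagged(self):
        net = self.make_net([("T1", "transit", 0.9), ("transit", "acetate", 0.9)])
        res = sm.scfa_neighborhood(net, ["acetate"]).set_index("node")
        assert res.loc["T1", "category"] == "indirect"
        assert bool(res.loc["T1", "via_transit_only"])

    def test_unknown_scfa_node_is_key_error(self):
        net = self.make_net([])
        with pytest.raises(KeyError):
            sm.scfa_neighborhood(net, ["lactate"])
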