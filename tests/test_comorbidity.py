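"""Comorbidity network construction: exact tests, weights, clustering."""

import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import comornet as cn
from comornet._fisher import fisher_exact_2x2
from comornet.comorbidity import breslow_day

from conftest import make_dm


# ----------------------------------------------------------------------
# oracles
# ----------------------------------------------------------------------
def fisher_oracle(a, b, c, d):
    """Literal two-sided Fisher p: enumerate all tables with the observed
    margins and sum the exact rational probabilities of those no more
    probable than the observed table."""
    n = a + b + c + d
    r, s = a + b, a + c
    denom = comb(n, s)
    p_obs = Fraction(comb(r, a) * comb(n - r, s - a), denom)
    total = Fraction(0)
    for k in range(max(0, r + s - n), min(r, s) + 1):
        p_k = Fraction(comb(r, k) * comb(n - r, s - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


def phi_closed_form(a, b, c, d):
    num = a * d - b * c
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / np.sqrt(den)


def bh_oracle(pvals):
    """BH step-up applied literally: q_i = min over k >= rank(i) of
    p_(k) * m / k, clipped at 1."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


# ----------------------------------------------------------------------
# pairwise association
# ----------------------------------------------------------------------
class TestPairwiseAssociation:
    def test_identical_columns_give_phi_one(self):
        x = np.zeros((40, 2), dtype=int)
        x[:15, 0] = x[:15, 1] = 1
        dm = make_dm(x)
        row = cn.pairwise_association(dm).iloc[0]
        assert row["phi"] == pytest.approx(1.0)
        assert row["p_fisher"] == pytest.approx(
            fisher_oracle(15, 0, 0, 25), abs=1e-15
        )

    def test_balanced_independent_table(self):
        # [[25,25],[25,25]]: no association, p = 1, phi = 0
        x = np.zeros((100, 2), dtype=int)
        x[:50, 0] = 1
        x[25:75, 1] = 1
        row = cn.pairwise_association(make_dm(x)).iloc[0]
        assert row["phi"] == pytest.approx(0.0, abs=1e-15)
        assert row["p_fisher"] == pytest.approx(1.0)

    def test_example_table_matches_oracles(self):
        # contingency [[10,10],[10,70]]
        a, b, c, d = 10, 10, 10, 70
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )
        x = np.zeros((100, 2), dtype=int)
        x[:20, 0] = 1  # disease A in 20 patients
        x[:10, 1] = 1  # overlap 10
        x[20:30, 1] = 1
        row = cn.pairwise_association(make_dm(x)).iloc[0]
        assert row["p_fisher"] == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)
        assert row["phi"] == pytest.approx(phi_closed_form(a, b, c, d), abs=1e-12)

    def test_phi_equals_pearson_correlation(self, dataset):
        assoc = cn.pairwise_association(dataset.cohort).head(30)
        dm = dataset.cohort
        for _, row in assoc.iterrows():
            r = np.corrcoef(dm.column(row["disease_a"]), dm.column(row["disease_b"]))
            assert row["phi"] == pytest.approx(r[0, 1], abs=1e-12)

    def test_symmetry_under_column_order(self):
        rng = np.random.default_rng(0)
        x = (rng.random((60, 4)) < 0.4).astype(int)
        names = [f"D{j:03d}" for j in range(4)]
        a = cn.pairwise_association(make_dm(x, diseases=names), min_prevalence=1)
        b = cn.pairwise_association(
            make_dm(x[:, ::-1].copy(), diseases=names[::-1]), min_prevalence=1
        )
        key = lambda df: df.assign(
            pair=[frozenset(t) for t in zip(df.disease_a, df.disease_b)]
        ).set_index("pair")
        merged = key(a).join(key(b), lsuffix="_a", rsuffix="_b")
        assert np.allclose(merged["phi_a"], merged["phi_b"])
        assert np.allclose(merged["p_fisher_a"], merged["p_fisher_b"])

    def test_degenerate_disease_reported_missing(self):
        x = np.zeros((30, 2), dtype=int)
        x[:, 0] = 1  # prevalence n: phi undefined
        x[:10, 1] = 1
        out = cn.pairwise_association(make_dm(x), min_prevalence=1)
        assert np.isnan(out["phi"].iloc[0]) and np.isnan(out["p_fisher"].iloc[0])

    @given(
        st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_fisher_matches_oracle_property(self, a, b, c, d):
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d) if a + b + c + d else 1.0, abs=1e-12
        )


# ----------------------------------------------------------------------
# BH adjustment
# ----------------------------------------------------------------------
class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.2], [0.2]),
            ([0.4, 0.4, 0.4, 0.4], [0.4, 0.4, 0.4, 0.4]),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert cn.bh_adjust(p) == pytest.approx(expected)

    def test_empty_input(self):
        assert len(cn.bh_adjust([])) == 0

    def test_matches_literal_stepup_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(rng.integers(1, 60))
            assert cn.bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_nan_passthrough(self):
        out = cn.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_oracle([0.01, 0.04]))


# ----------------------------------------------------------------------
# network construction
# ----------------------------------------------------------------------
def _assoc_table(rows):
    return pd.DataFrame(
        rows,
        columns=["disease_a", "disease_b", "n11", "n10", "n01", "n00",
                 "p_fisher", "phi"],
    )


class TestBuildNetwork:
    def test_equal_phi_gives_equal_weights_and_zero_scores(self):
        rows = [
            ("A", "B", 30, 10, 10, 50, 1e-9, 0.4),
            ("B", "C", 30, 10, 10, 50, 1e-9, 0.4),
            ("A", "C", 30, 10, 10, 50, 1e-9, 0.4),
        ]
        net = cn.build_network(_assoc_table(rows), alpha=0.01)
        w = [d["W"] for _, _, d in net.graph.edges(data=True)]
        s = [d["S"] for _, _, d in net.graph.edges(data=True)]
        assert np.ptp(w) == pytest.approx(0.0)
        assert s == pytest.approx([0.0, 0.0, 0.0])

    def test_retention_requires_positive_phi_and_small_q(self):
        rows = [
            ("A", "B", 30, 10, 10, 50, 1e-9, 0.4),
            ("A", "C", 5, 35, 35, 25, 1e-9, -0.4),  # negative phi: excluded
            ("B", "C", 20, 20, 20, 40, 0.5, 0.1),  # non-significant
        ]
        net = cn.build_network(_assoc_table(rows), alpha=0.01)
        assert set(map(frozenset, net.graph.edges())) == {frozenset(("A", "B"))}

    def test_edge_retention_monotone_in_alpha(self, dataset):
        assoc = cn.pairwise_association(dataset.cohort)
        strict = cn.build_network(assoc, alpha=1e-6)
        loose = cn.build_network(assoc, alpha=1e-3)
        e_strict = set(map(frozenset, strict.graph.edges()))
        e_loose = set(map(frozenset, loose.graph.edges()))
        assert e_strict <= e_loose

    def test_empty_network_is_warning_not_failure(self):
        rows = [("A", "B", 10, 10, 10, 10, 0.9, 0.01)]
        with pytest.warns(UserWarning, match="no edges"):
            net = cn.build_network(_assoc_table(rows), alpha=1e-4)
        assert net.n_edges == 0 and net.n_nodes == 2

    def test_planted_partition_has_high_modularity(self, dataset, disease_network):
        truth = dataset.truth
        g = disease_network.graph
        communities = {}
        for d in g.nodes():
            communities.setdefault(truth.cluster_of_disease[d], set()).add(d)
        q = nx.community.modularity(g, communities.values(), weight="W")
        assert q > 0.2

    def test_scaling_variants_differ_but_rank_similarly(self, dataset):
        assoc = cn.pairwise_association(dataset.cohort)
        geo = cn.build_network(assoc, scaling="geometric")
        ari = cn.build_network(assoc, scaling="arithmetic")
        eg = geo.edges_table().set_index(["disease_a", "disease_b"])["W"]
        ea = ari.edges_table().set_index(["disease_a", "disease_b"])["W"]
        assert eg.index.equals(ea.index)
        assert stats.spearmanr(eg, ea).statistic > 0.95


# ----------------------------------------------------------------------
# centralities
# ----------------------------------------------------------------------
def _net_from_edges(edges, distances=None):
    """Toy network; ``edges`` are (u, v, W), ``distances`` optional
    explicit S values (default 1, i.e. unweighted shortest paths)."""
    g = nx.Graph()
    for k, (u, v, w) in enumerate(edges):
        s = 1.0 if distances is None else distances[k]
        g.add_edge(u, v, W=w, S=s)
    return cn.DiseaseNetwork(g)


class TestCentralities:
    def test_star_betweenness(self):
        net = _net_from_edges([("c", f"l{i}", 1.0) for i in range(4)])
        table = cn.centralities(net)
        assert table.nodes.loc["c", "betweenness"] == pytest.approx(6.0)
        assert (table.nodes.drop("c")["betweenness"] == 0).all()

    def test_triangle_transitivity(self):
        net = _net_from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        assert cn.centralities(net).transitivity == pytest.approx(1.0)

    def test_path_betweenness_matches_enumeration(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0.5, 2.0, 4)
        nodes = list("abcde")
        net = _net_from_edges(
            [(nodes[i], nodes[i + 1], w[i]) for i in range(4)],
            distances=rng.uniform(0.1, 1.0, 4),
        )
        table = cn.centralities(net)
        # on a path every interior node lies on all paths crossing it
        expected = {"a": 0, "b": 3, "c": 4, "d": 3, "e": 0}
        for node, exp in expected.items():
            assert table.nodes.loc[node, "betweenness"] == pytest.approx(exp)

    def test_disconnected_graph_uses_harmonic_closeness(self):
        net = _net_from_edges([("a", "b", 1.0), ("c", "d", 1.0)])
        assert cn.centralities(net).closeness_variant == "harmonic"


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------
class TestDetectClusters:
    def _two_cliques(self):
        edges = [(f"a{i}", f"a{j}", 1.0) for i in range(4) for j in range(i + 1, 4)]
        edges += [(f"b{i}", f"b{j}", 1.0) for i in range(4) for j in range(i + 1, 4)]
        edges += [("a0", "b0", 0.05)]
        return _net_from_edges(edges)

    @pytest.mark.parametrize("algorithm", ["leiden", "louvain"])
    def test_two_cliques_two_clusters(self, algorithm):
        cs = cn.detect_clusters(self._two_cliques(), algorithm=algorithm, seed=1)
        assert cs.n_clusters == 2
        groups = {}
        for d, c in cs.membership.items():
            groups.setdefault(c, set()).add(d)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(f"a{i}" for i in range(4)),
            frozenset(f"b{i}" for i in range(4)),
        }

    def test_deterministic_under_seed(self, disease_network):
        a = cn.detect_clusters(disease_network, seed=7)
        b = cn.detect_clusters(disease_network, seed=7)
        assert a.membership == b.membership

    def test_unknown_algorithm_lists_supported(self, disease_network):
        with pytest.raises(ValueError, match="leiden"):
            cn.detect_clusters(disease_network, algorithm="kmeans")

    def test_cluster_ids_contiguous(self, clusters):
        ids = sorted(set(clusters.membership.values()))
        assert ids == list(range(len(ids)))


# ----------------------------------------------------------------------
# network comparison
# ----------------------------------------------------------------------
def deltacon_oracle(g1, g2, nodes):
    """Dense re-implementation from the definitions: affinity
    S = (I + eps^2 D - eps A)^-1 per graph, Matusita root-euclidean
    distance, similarity 1/(1+d)."""
    mats = []
    for g in (g1, g2):
        a = np.zeros((len(nodes), len(nodes)))
        idx = {n: i for i, n in enumerate(nodes)}
        for u, v in g.edges():
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
        deg = a.sum(1)
        eps = 1 / (1 + deg.max())
        mats.append(np.linalg.solve(np.eye(len(nodes)) + eps**2 * np.diag(deg) - eps * a,
                                    np.eye(len(nodes))))
    s1, s2 = mats
    d = np.sqrt(np.sum((np.sign(s1) * np.sqrt(abs(s1)) - np.sign(s2) * np.sqrt(abs(s2))) ** 2))
    return 1 / (1 + d)


class TestCompareNetworks:
    def test_self_similarity(self, disease_network):
        j, d = cn.compare_networks(disease_network, disease_network)
        assert j == pytest.approx(1.0) and d == pytest.approx(1.0)

    def test_edge_disjoint_graphs(self):
        g1 = nx.Graph([("a", "b"), ("c", "d")])
        g2 = nx.Graph([("a", "c"), ("b", "d")])
        j, _ = cn.compare_networks(g1, g2)
        assert j == 0.0

    def test_deltacon_matches_dense_oracle(self):
        g1 = nx.cycle_graph(6)
        g2 = nx.path_graph(6)
        nodes = sorted(set(g1) | set(g2))
        _, d = cn.compare_networks(g1, g2)
        assert d == pytest.approx(deltacon_oracle(g1, g2, nodes), abs=1e-10)

    def test_empty_union_reports_missing(self):
        j, _ = cn.compare_networks(nx.empty_graph(3), nx.empty_graph(3))
        assert np.isnan(j)


# ----------------------------------------------------------------------
# odds-ratio homogeneity
# ----------------------------------------------------------------------
def _dm_from_strata(t1, t2):
    rows = []
    for stratum, t in (("s1", t1), ("s2", t2)):
        for (xa, xb), count in zip([(1, 1), (1, 0), (0, 1), (0, 0)], t):
            rows += [(xa, xb, stratum)] * count
    occ = np.array([[r[0], r[1]] for r in rows])
    cov = pd.DataFrame({"grp": [r[2] for r in rows]})
    return make_dm(occ, covariates=cov, diseases=["X", "Y"])


def breslow_day_oracle(tables):
    """Hand computation of the Breslow-Day statistic (no Tarone)."""
    ns = [t.sum() for t in tables]
    num = sum(t[0, 0] * t[1, 1] / n for t, n in zip(tables, ns))
    den = sum(t[0, 1] * t[1, 0] / n for t, n in zip(tables, ns))
    or_mh = num / den
    stat = 0.0
    for t, n in zip(tables, ns):
        a = t[0, 0]
        r, s = t[0].sum(), t[:, 0].sum()
        qa, qb, qc = or_mh - 1, -(or_mh * (r + s) + n - r - s), or_mh * r * s
        if abs(qa) < 1e-12:
            a_exp = -qc / qb
        else:
            disc = np.sqrt(qb**2 - 4 * qa * qc)
            cands = [(-qb - disc) / (2 * qa), (-qb + disc) / (2 * qa)]
            a_exp = next(
                x for x in cands if max(0, r + s - n) - 1e-9 <= x <= min(r, s) + 1e-9
            )
        var = 1 / (1 / a_exp + 1 / (r - a_exp) + 1 / (s - a_exp)
                   + 1 / (n - r - s + a_exp))
        stat += (a - a_exp) ** 2 / var
    return stat


class TestOrHomogeneity:
    def test_identical_strata_statistic_zero(self):
        dm = _dm_from_strata([20, 10, 10, 20], [20, 10, 10, 20])
        res = cn.or_homogeneity(dm, "grp", [("X", "Y")], tarone=False)
        assert res["bd_statistic"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["p_bd"].iloc[0] == pytest.approx(1.0)

    def test_opposite_strata_match_hand_formula(self):
        t1 = np.array([[20, 10], [10, 20]], float)
        t2 = np.array([[10, 20], [20, 10]], float)
        dm = _dm_from_strata([20, 10, 10, 20], [10, 20, 20, 10])
        res = cn.or_homogeneity(dm, "grp", [("X", "Y")], tarone=False)
        assert res["bd_statistic"].iloc[0] == pytest.approx(
            breslow_day_oracle([t1, t2]), rel=1e-9
        )
        assert res["p_bd"].iloc[0] < 0.05

    def test_type_one_error_calibrated_under_common_or(self):
        rng = np.random.default_rng(1)
        rej = 0
        reps = 1000
        for _ in range(reps):
            tabs = []
            for n in (200, 200):
                x = rng.random(n) < 0.4
                p_y = np.where(x, 0.5, 1 / 3)  # common OR = 2 in both strata
                y = rng.random(n) < p_y
                tabs.append(
                    np.array(
                        [[np.sum(x & y), np.sum(x & ~y)],
                         [np.sum(~x & y), np.sum(~x & ~y)]], float
                    )
                )
            _, p = breslow_day(tabs, tarone=True)
            rej += p < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_zero_margin_stratum_skipped_with_reason(self):
        dm = _dm_from_strata([20, 10, 10, 20], [0, 0, 15, 15])
        res = cn.or_homogeneity(dm, "grp", [("X", "Y")])
        assert res["skip_reason"].iloc[0] == "zero margin in a stratum"
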