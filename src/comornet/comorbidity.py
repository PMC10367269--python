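"""Weighted disease co-occurrence (comorbidity) networks.

Diseases are nodes; an edge connects two diseases whose co-occurrence
across patients is statistically dependent (two-sided Fisher exact test,
Benjamini-Hochberg corrected) and positively correlated (phi > 0). Edge
weights are phi correlations rescaled by per-disease mean correlation to
reduce hub bias; graph-distance metrics run on the complementary score
S = max(W) - W, so that strong comorbid ties are short.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from ._fisher import fisher_exact_2x2
from .cohort import DiagnosisMatrix

__all__ = [
    "pairwise_association",
    "bh_adjust",
    "build_network",
    "DiseaseNetwork",
    "centralities",
    "CentralityTable",
    "detect_clusters",
    "DiseaseClusterSet",
    "compare_networks",
    "or_homogeneity",
]


# ----------------------------------------------------------------------
# pairwise association
# ----------------------------------------------------------------------
def pairwise_association(
    dm: DiagnosisMatrix, min_prevalence: int = 5
) -> pd.DataFrame:
    """Fisher exact p and phi correlation for every unordered disease pair.

    Parameters
    ----------
    dm : DiagnosisMatrix
        Binary cohort matrix.
    min_prevalence : int
        Diseases recorded in fewer patients than this are not tested.

    Returns
    -------
    pandas.DataFrame
        One row per unordered pair of tested diseases with columns
        ``disease_a``, ``disease_b``, the 2x2 contingency counts
        ``n11, n10, n01, n00`` (patients with both / only a / only b /
        neither), ``p_fisher`` and ``phi``. Degenerate diseases
        (prevalence 0 or equal to the cohort size) yield missing
        statistics and are never edge-eligible.
    """
    if dm.n_diseases < 2 or dm.n_patients < 2:
        raise ValueError("need at least 2 diseases and 2 patients")
    n = dm.n_patients
    X = dm.occurrence.astype(np.int64)
    prev = np.asarray(X.sum(axis=0)).ravel()
    keep = np.flatnonzero(prev >= min_prevalence)
    co = np.asarray((X[:, keep].T @ X[:, keep]).todense())
    rows = []
    codes = np.asarray(dm.diseases, dtype=object)[keep]
    kprev = prev[keep]
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            n11 = int(co[i, j])
            n10 = int(kprev[i] - n11)
            n01 = int(kprev[j] - n11)
            n00 = int(n - n11 - n10 - n01)
            degenerate = kprev[i] in (0, n) or kprev[j] in (0, n)
            if degenerate:
                p = np.nan
                phi = np.nan
            else:
                p = fisher_exact_2x2(n11, n10, n01, n00)
                num = n11 * n00 - n10 * n01
                den = kprev[i] * kprev[j] * (n - kprev[i]) * (n - kprev[j])
                phi = num / np.sqrt(float(den))
            rows.append((codes[i], codes[j], n11, n10, n01, n00, p, phi))
    return pd.DataFrame(
        rows,
        columns=[
            "disease_a",
            "disease_b",
            "n11",
            "n10",
            "n01",
            "n00",
            "p_fisher",
            "phi",
        ],
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved.

    Missing p-values propagate as missing and do not enter the correction.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ----------------------------------------------------------------------
# network construction
# ----------------------------------------------------------------------
@dataclass
class DiseaseNetwork:
    """Undirected weighted disease graph with per-edge statistics.

    Edge attributes: ``p`` (Fisher), ``q`` (BH), ``phi``, ``W`` (scaled
    phi weight) and ``S = max(W) - W`` (distance score). Node attributes:
    ``prevalence`` and optional ``category``.
    """

    graph: nx.Graph
    alpha: float = 1e-4
    scaling: str = "geometric"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_table(self) -> pd.DataFrame:
        recs = [
            {"disease_a": u, "disease_b": v, **attrs}
            for u, v, attrs in self.graph.edges(data=True)
        ]
        cols = ["disease_a", "disease_b", "p", "q", "phi", "W", "S"]
        return pd.DataFrame(recs, columns=cols)

    def write_edgelist(self, path: str | Path) -> None:
        self.edges_table().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    assoc: pd.DataFrame,
    alpha: float = 1e-4,
    scaling: str = "geometric",
    categories: dict[str, str] | None = None,
) -> DiseaseNetwork:
    """Assemble the comorbidity network from the pairwise association table.

    Retains pairs with BH-adjusted q below ``alpha`` and positive phi.
    Each retained edge weight is the phi correlation rescaled by the mean
    retained-positive phi of its two endpoint diseases: with
    ``scaling="geometric"`` (default) ``W_ij = phi_ij / sqrt(m_i * m_j)``,
    with ``scaling="arithmetic"`` ``W_ij = phi_ij / ((m_i + m_j) / 2)``.
    The distance score ``S = max(W) - W`` is attached per edge.
    """
    if scaling not in ("geometric", "arithmetic"):
        raise ValueError("scaling must be 'geometric' or 'arithmetic'")
    assoc = assoc.copy()
    assoc["q"] = bh_adjust(assoc["p_fisher"].to_numpy())
    retained = assoc[(assoc["q"] < alpha) & (assoc["phi"] > 0)]

    g = nx.Graph()
    prevalence: dict[str, int] = {}
    for col_a, col_n in (("disease_a", "n10"), ("disease_b", "n01")):
        both_plus = assoc["n11"] + assoc[col_n]
        for code, p in zip(assoc[col_a], both_plus):
            prevalence[code] = int(p)
    for code, prev in prevalence.items():
        g.add_node(code, prevalence=prev)
        if categories and code in categories:
            g.nodes[code]["category"] = categories[code]

    if len(retained) == 0:
        warnings.warn("no edges retained at alpha=%g; empty network" % alpha)
        return DiseaseNetwork(g, alpha=alpha, scaling=scaling)

    # mean retained-positive phi per endpoint disease
    phi_sum: dict[str, float] = {}
    phi_cnt: dict[str, int] = {}
    for a, b, phi in zip(retained["disease_a"], retained["disease_b"], retained["phi"]):
        for code in (a, b):
            phi_sum[code] = phi_sum.get(code, 0.0) + phi
            phi_cnt[code] = phi_cnt.get(code, 0) + 1
    mean_phi = {c: phi_sum[c] / phi_cnt[c] for c in phi_sum}

    W = []
    for a, b, phi in zip(retained["disease_a"], retained["disease_b"], retained["phi"]):
        if scaling == "geometric":
            W.append(phi / np.sqrt(mean_phi[a] * mean_phi[b]))
        else:
            W.append(phi / ((mean_phi[a] + mean_phi[b]) / 2.0))
    W = np.asarray(W)
    S = W.max() - W
    for (_, row), w, s in zip(retained.iterrows(), W, S):
        g.add_edge(
            row["disease_a"],
            row["disease_b"],
            p=float(row["p_fisher"]),
            q=float(row["q"]),
            phi=float(row["phi"]),
            W=float(w),
            S=float(s),
        )
    return DiseaseNetwork(g, alpha=alpha, scaling=scaling)


# ----------------------------------------------------------------------
# characterization
# ----------------------------------------------------------------------
class CentralityTable(NamedTuple):
    nodes: pd.DataFrame  # degree, strength, betweenness, closeness
    transitivity: float
    closeness_variant: str  # "standard" or "harmonic" (disconnected graphs)


def centralities(net: DiseaseNetwork) -> CentralityTable:
    """Node centralities and global transitivity.

    Shortest-path metrics (betweenness, closeness) use the edge distance
    ``S``; degree is unweighted; strength sums ``W``. On disconnected
    graphs closeness switches to the harmonic variant (finite for
    unreachable pairs) and the variant used is recorded.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degree = dict(g.degree())
    strength = dict(g.degree(weight="W"))
    betweenness = nx.betweenness_centrality(g, weight="S", normalized=False)
    if nx.is_connected(g):
        closeness = nx.closeness_centrality(g, distance="S")
        variant = "standard"
    else:
        closeness = nx.harmonic_centrality(g, distance="S")
        variant = "harmonic"
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "strength": pd.Series(strength),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
        }
    )
    df.index.name = "disease"
    return CentralityTable(df, nx.transitivity(g), variant)


@dataclass
class DiseaseClusterSet:
    """Partition of the (non-isolated) disease nodes into clusters."""

    membership: dict[str, int]
    algorithm: str
    quality: float  # weighted modularity
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.membership.values()))

    def members(self, cluster: int) -> set[str]:
        return {d for d, c in self.membership.items() if c == cluster}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"disease": list(self.membership), "cluster": list(self.membership.values())}
        )


_CLUSTER_ALGORITHMS = ("leiden", "louvain")


def detect_clusters(
    net: DiseaseNetwork, algorithm: str = "leiden", seed: int = 0
) -> DiseaseClusterSet:
    """Weighted modularity clustering of the comorbidity network.

    ``leiden`` (default) uses the Leiden algorithm, ``louvain`` igraph's
    multilevel algorithm; both optimize modularity with edge weight ``W``
    and are deterministic under a fixed seed. Isolated nodes are left out
    of the partition; cluster ids are relabelled 0..k-1 by decreasing size.
    """
    if algorithm not in _CLUSTER_ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; supported: {_CLUSTER_ALGORITHMS}"
        )
    sub = net.graph.edge_subgraph(net.graph.edges())  # drop isolated nodes
    if sub.number_of_edges() == 0:
        raise ValueError("network has no edges to cluster")
    nodes = sorted(sub.nodes())
    index = {d: i for i, d in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in sub.edges()]
    weights = [sub.edges[u, v]["W"] for u, v in sub.edges()]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    if algorithm == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            weights="weight",
            seed=seed,
            n_iterations=-1,
        )
        membership = part.membership
    else:
        state = random.getstate()
        try:
            random.seed(seed)
            ig.set_random_number_generator(random)
            membership = g.community_multilevel(weights="weight").membership
        finally:
            ig.set_random_number_generator(None)
            random.setstate(state)
    quality = g.modularity(membership, weights="weight")
    # contiguous ids ordered by decreasing cluster size (ties by min node)
    sizes: dict[int, int] = {}
    for m in membership:
        sizes[m] = sizes.get(m, 0) + 1
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    relabel = {old: new for new, old in enumerate(order)}
    mapping = {nodes[i]: relabel[m] for i, m in enumerate(membership)}
    return DiseaseClusterSet(mapping, algorithm, quality)


# ----------------------------------------------------------------------
# network comparison
# ----------------------------------------------------------------------
def _deltacon_affinity(adj: np.ndarray) -> np.ndarray:
    """Fast-belief-propagation node affinity S = (I + eps^2 D - eps A)^-1."""
    deg = adj.sum(axis=1)
    eps = 1.0 / (1.0 + deg.max()) if len(deg) else 1.0
    n = adj.shape[0]
    m = np.eye(n) + eps**2 * np.diag(deg) - eps * adj
    return np.linalg.inv(m)


def compare_networks(
    a: DiseaseNetwork | nx.Graph, b: DiseaseNetwork | nx.Graph
) -> tuple[float, float]:
    """Edge Jaccard and DeltaCon similarity of two disease networks.

    Both graphs are unioned onto a shared node universe and treated as
    unweighted. Edge Jaccard is |E_a & E_b| / |E_a | E_b| (missing when
    both edge sets are empty). DeltaCon is 1 / (1 + d) where d is the
    Matusita (root-euclidean) distance between the two fast-belief-
    propagation node affinity matrices.
    """
    ga = a.graph if isinstance(a, DiseaseNetwork) else a
    gb = b.graph if isinstance(b, DiseaseNetwork) else b
    nodes = sorted(set(ga.nodes()) | set(gb.nodes()))
    ea = {frozenset(e) for e in ga.edges()}
    eb = {frozenset(e) for e in gb.edges()}
    union = ea | eb
    jacc = len(ea & eb) / len(union) if union else np.nan

    idx = {d: i for i, d in enumerate(nodes)}
    adj_a = np.zeros((len(nodes), len(nodes)))
    adj_b = np.zeros_like(adj_a)
    for adj, es in ((adj_a, ea), (adj_b, eb)):
        for e in es:
            u, v = tuple(e)
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = 1.0
    s_a = _deltacon_affinity(adj_a)
    s_b = _deltacon_affinity(adj_b)
    d = np.sqrt(((np.sqrt(np.abs(s_a)) * np.sign(s_a)
                  - np.sqrt(np.abs(s_b)) * np.sign(s_b)) ** 2).sum())
    return jacc, 1.0 / (1.0 + d)


# ----------------------------------------------------------------------
# odds-ratio homogeneity across strata
# ----------------------------------------------------------------------
def breslow_day(
    tables: list[np.ndarray], tarone: bool = True
) -> tuple[float, float]:
    """Breslow-Day chi-square test of odds-ratio homogeneity.

    ``tables`` is a list of K 2x2 tables. The common odds ratio is the
    Mantel-Haenszel estimate; for each stratum the expected [0, 0] cell
    under that common OR solves the standard quadratic (or its linear
    limit when the common OR is 1, where the closed form is the
    independence expectation r*s/n). With ``tarone`` the statistic gets
    the Tarone correction. Returns (statistic, p) on K - 1 df.
    """
    tabs = [np.asarray(t, dtype=float) for t in tables]
    if len(tabs) < 2:
        raise ValueError("need at least 2 strata")
    ns = [t.sum() for t in tabs]
    or_mh = sum(t[0, 0] * t[1, 1] / n for t, n in zip(tabs, ns)) / sum(
        t[0, 1] * t[1, 0] / n for t, n in zip(tabs, ns)
    )
    stat = 0.0
    resid_sum = 0.0
    var_sum = 0.0
    for t, n in zip(tabs, ns):
        a = t[0, 0]
        r = t[0, 0] + t[0, 1]
        s = t[0, 0] + t[1, 0]
        # expected a: OR (r - x)(s - x) = x (n - r - s + x)
        qa = or_mh - 1.0
        qb = -(or_mh * (r + s) + n - r - s)
        qc = or_mh * r * s
        if abs(qa) < 1e-12:
            a_exp = -qc / qb
        else:
            disc = np.sqrt(qb**2 - 4 * qa * qc)
            roots = [(-qb - disc) / (2 * qa), (-qb + disc) / (2 * qa)]
            lo, hi = max(0.0, r + s - n), min(r, s)
            a_exp = next(x for x in roots if lo - 1e-9 <= x <= hi + 1e-9)
        var = 1.0 / (
            1.0 / a_exp
            + 1.0 / (r - a_exp)
            + 1.0 / (s - a_exp)
            + 1.0 / (n - r - s + a_exp)
        )
        stat += (a - a_exp) ** 2 / var
        resid_sum += a - a_exp
        var_sum += var
    if tarone:
        stat -= resid_sum**2 / var_sum
    stat = max(stat, 0.0)
    return float(stat), float(chi2.sf(stat, df=len(tabs) - 1))


def or_homogeneity(
    dm: DiagnosisMatrix,
    stratum: str,
    pairs: list[tuple[str, str]],
    tarone: bool = True,
) -> pd.DataFrame:
    """Breslow-Day test of odds-ratio homogeneity across a 2-level stratum.

    For every disease pair the 2x2 co-occurrence table is formed within
    each stratum level and the Breslow-Day chi-square statistic (with the
    Tarone correction when ``tarone``) tests whether the odds ratio is the
    same in both strata. A +0.5 continuity correction is applied to a
    stratum table containing a zero cell (recorded per pair). P-values are
    BH-adjusted across pairs; pairs whose stratum table has a zero margin
    are skipped with a reason.
    """
    levels = pd.unique(dm.covariates[stratum].dropna())
    if len(levels) != 2:
        raise ValueError(f"stratum {stratum!r} must have exactly 2 levels, got {levels}")
    masks = [
        (dm.covariates[stratum] == lev).to_numpy(dtype=bool) for lev in levels
    ]
    rows = []
    d_idx = {d: j for j, d in enumerate(dm.diseases)}
    X = dm.occurrence.tocsc()
    for da, db in pairs:
        xa = np.asarray(X[:, d_idx[da]].todense()).ravel()
        xb = np.asarray(X[:, d_idx[db]].todense()).ravel()
        tables = []
        ors = []
        corrected = False
        reason = None
        for mask in masks:
            a = int(((xa == 1) & (xb == 1) & mask).sum())
            b_ = int(((xa == 1) & (xb == 0) & mask).sum())
            c = int(((xa == 0) & (xb == 1) & mask).sum())
            d = int(((xa == 0) & (xb == 0) & mask).sum())
            if (a + b_) == 0 or (c + d) == 0 or (a + c) == 0 or (b_ + d) == 0:
                reason = "zero margin in a stratum"
                break
            t = np.array([[a, b_], [c, d]], dtype=float)
            if (t == 0).any():
                t = t + 0.5
                corrected = True
            tables.append(t)
            ors.append(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
        if reason is not None:
            rows.append((da, db, np.nan, np.nan, np.nan, np.nan, False, reason))
            continue
        stat, p = breslow_day(tables, tarone=tarone)
        rows.append((da, db, ors[0], ors[1], stat, p, corrected, None))
    out = pd.DataFrame(
        rows,
        columns=[
            "disease_a", "disease_b", "or_stratum1", "or_stratum2",
            "bd_statistic", "p_bd", "continuity_corrected", "skip_reason",
        ],
    )
    out["q_bh"] = bh_adjust(out["p_bd"].to_numpy())
    out.attrs["stratum_levels"] = list(levels)
    return out
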