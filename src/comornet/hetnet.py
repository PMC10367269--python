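"""Multiplex-heterogeneous disease-gene network assembly.

Two multiplexes — a disease network (comorbidity layer plus an optional
phenotype-similarity layer) and a gene network (pathway, PPI, ontology
layers) — joined by a bipartite disease-gene association layer filtered by
a confidence score. Gene layers can additionally be restricted to an
expression whitelist (e.g. genes expressed in the tissue of interest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "LayerSpec",
    "HetNet",
    "filter_bipartite",
    "filter_expression",
    "assemble",
    "layer_stats",
    "disease_layer_from_network",
]


@dataclass
class LayerSpec:
    """One undirected layer of a multiplex: a named weighted edge list.

    ``edges`` has columns ``source``, ``target``, ``weight``; weights are
    positive. Self-loops and duplicate (unordered) edges are removed on
    construction, keeping the maximum weight of duplicates.
    """

    name: str
    kind: str  # "disease" | "gene"
    edges: pd.DataFrame
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("disease", "gene"):
            raise ValueError("kind must be 'disease' or 'gene'")
        df = self.edges.copy()
        if "weight" not in df.columns:
            df["weight"] = 1.0
        df = df[df["source"] != df["target"]]
        if (df["weight"] <= 0).any():
            raise ValueError(f"layer {self.name!r}: weights must be positive")
        lo = df[["source", "target"]].min(axis=1)
        hi = df[["source", "target"]].max(axis=1)
        df = df.assign(source=lo, target=hi)
        df = (
            df.groupby(["source", "target"], as_index=False)["weight"]
            .max()
            .sort_values(["source", "target"], ignore_index=True)
        )
        self.edges = df

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["source"]) | set(self.edges["target"])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for s, t, w in self.edges.itertuples(index=False):
            g.add_edge(s, t, weight=float(w))
        return g


def disease_layer_from_network(net, name: str = "comorbidity") -> LayerSpec:
    """Wrap a comorbidity :class:`~comornet.comorbidity.DiseaseNetwork`
    as a disease layer, using W as the edge weight."""
    rows = [
        (u, v, attrs["W"]) for u, v, attrs in net.graph.edges(data=True)
    ]
    return LayerSpec(
        name, "disease", pd.DataFrame(rows, columns=["source", "target", "weight"])
    )


# ----------------------------------------------------------------------
def filter_bipartite(raw: pd.DataFrame, min_conf: float = 0.29) -> pd.DataFrame:
    """Keep disease-gene associations with confidence strictly above
    ``min_conf``; duplicate (disease, gene) rows collapse to their maximum
    score."""
    df = raw[raw["score"] > min_conf]
    return (
        df.groupby(["disease", "gene"], as_index=False)["score"]
        .max()
        .sort_values(["disease", "gene"], ignore_index=True)
    )


def filter_expression(
    layers: list[LayerSpec], whitelist: set[str]
) -> list[LayerSpec]:
    """Restrict gene layers to whitelisted genes (e.g. expressed in the
    target tissue); edges incident to removed genes are dropped.

    The whitelist is typically the union of the available expression
    evidence sources (proteome, transcriptome, disease-state
    transcriptome); build that union before calling.
    """
    if not whitelist:
        warnings.warn("empty whitelist: all gene layers will be empty")
    out = []
    for layer in layers:
        if layer.kind != "gene":
            raise ValueError("filter_expression applies to gene layers only")
        keep = layer.edges["source"].isin(whitelist) & layer.edges[
            "target"
        ].isin(whitelist)
        edges = layer.edges[keep].reset_index(drop=True)
        if len(edges) == 0:
            warnings.warn(f"layer {layer.name!r} empty after expression filter")
        out.append(LayerSpec(layer.name, "gene", edges, layer.weighted))
    return out


# ----------------------------------------------------------------------
@dataclass
class HetNet:
    """Assembled multiplex-heterogeneous network.

    Universes are the sorted unions of the respective layer node sets;
    bipartite edges with an endpoint outside either universe are dropped
    at assembly (``n_dropped_bipartite``). Layer weights are normalized to
    a maximum of 1 per layer so no layer dominates transition
    probabilities.
    """

    disease_layers: list[LayerSpec]
    gene_layers: list[LayerSpec]
    bipartite: pd.DataFrame  # disease, gene, score
    disease_universe: list[str] = field(default_factory=list)
    gene_universe: list[str] = field(default_factory=list)
    n_dropped_bipartite: int = 0

    def layer(self, name: str) -> LayerSpec:
        for sp in self.disease_layers + self.gene_layers:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def replace_disease_layer(self, layer: LayerSpec) -> "HetNet":
        """Return a new HetNet with the same-named disease layer swapped."""
        layers = [layer if sp.name == layer.name else sp for sp in self.disease_layers]
        return assemble(layers, self.gene_layers, self.bipartite)

    def drop_disease_layer(self, name: str) -> "HetNet":
        layers = [sp for sp in self.disease_layers if sp.name != name]
        if not layers:
            raise ValueError("cannot drop the only disease layer")
        return assemble(layers, self.gene_layers, self.bipartite)

    def without_bipartite_for(self, disease: str) -> "HetNet":
        """Copy with all bipartite links of one disease removed
        (leave-one-out evaluation); layers are shared, not copied."""
        bip = self.bipartite[self.bipartite["disease"] != disease].reset_index(
            drop=True
        )
        return HetNet(
            self.disease_layers,
            self.gene_layers,
            bip,
            self.disease_universe,
            self.gene_universe,
            self.n_dropped_bipartite,
        )

    # ------------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Serialize as one long edge table with a layer column."""
        frames = []
        for sp in self.disease_layers + self.gene_layers:
            df = sp.edges.copy()
            df.insert(0, "kind", sp.kind)
            df.insert(0, "layer", sp.name)
            frames.append(df)
        bip = self.bipartite.rename(
            columns={"disease": "source", "gene": "target", "score": "weight"}
        )
        bip.insert(0, "kind", "bipartite")
        bip.insert(0, "layer", "bipartite")
        pd.concat(frames + [bip], ignore_index=True).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read(cls, path: str | Path) -> "HetNet":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        dlayers, glayers = [], []
        for (name, kind), grp in df.groupby(["layer", "kind"], sort=False):
            if kind == "bipartite":
                continue
            sp = LayerSpec(name, kind, grp[["source", "target", "weight"]])
            (dlayers if kind == "disease" else glayers).append(sp)
        bip = df[df["kind"] == "bipartite"].rename(
            columns={"source": "disease", "target": "gene", "weight": "score"}
        )[["disease", "gene", "score"]]
        return assemble(dlayers, glayers, bip)


def assemble(
    disease_layers: list[LayerSpec],
    gene_layers: list[LayerSpec],
    bipartite: pd.DataFrame,
) -> HetNet:
    """Assemble layers and bipartite associations into a HetNet.

    Node universes are the per-kind unions of layer nodes. Disease and
    gene namespaces must be disjoint. Per-layer weights are normalized to
    max 1; bipartite edges with endpoints outside the universes are
    dropped and counted.
    """
    if not disease_layers or not gene_layers:
        raise ValueError("need at least one disease layer and one gene layer")
    d_nodes: set[str] = set()
    for sp in disease_layers:
        if sp.kind != "disease":
            raise ValueError(f"layer {sp.name!r} is not a disease layer")
        d_nodes |= sp.nodes
    g_nodes: set[str] = set()
    for sp in gene_layers:
        if sp.kind != "gene":
            raise ValueError(f"layer {sp.name!r} is not a gene layer")
        g_nodes |= sp.nodes
    collision = d_nodes & g_nodes
    if collision:
        raise ValueError(
            f"disease/gene namespace collision on {len(collision)} node id(s), "
            f"e.g. {sorted(collision)[:3]}"
        )

    def _normalize(sp: LayerSpec) -> LayerSpec:
        edges = sp.edges.copy()
        wmax = edges["weight"].max()
        if len(edges) and wmax > 0:
            edges["weight"] = edges["weight"] / wmax
        return LayerSpec(sp.name, sp.kind, edges, sp.weighted)

    dls = [_normalize(sp) for sp in disease_layers]
    gls = [_normalize(sp) for sp in gene_layers]

    bip = bipartite.copy()
    inside = bip["disease"].isin(d_nodes) & bip["gene"].isin(g_nodes)
    n_dropped = int((~inside).sum())
    bip = (
        bip[inside]
        .groupby(["disease", "gene"], as_index=False)["score"]
        .max()
        .sort_values(["disease", "gene"], ignore_index=True)
    )
    return HetNet(dls, gls, bip, sorted(d_nodes), sorted(g_nodes), n_dropped)


# ----------------------------------------------------------------------
def layer_stats(net: HetNet) -> pd.DataFrame:
    """Per-layer size and topology statistics.

    Edge density is the percentage of possible edges among the layer's
    own nodes; transitivity is the global clustering coefficient; degree
    assortativity is the Pearson correlation of endpoint degrees over
    edges.
    """
    rows = []
    for sp in net.disease_layers + net.gene_layers:
        g = sp.to_graph()
        n, m = g.number_of_nodes(), g.number_of_edges()
        density = 100.0 * m / (n * (n - 1) / 2.0) if n > 1 else np.nan
        if m > 0 and n > 1:
            trans = nx.transitivity(g)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant-degree graphs
                try:
                    assort = nx.degree_assortativity_coefficient(g)
                except Exception:
                    assort = np.nan
        else:
            trans, assort = np.nan, np.nan
        rows.append(
            {
                "layer": sp.name,
                "kind": sp.kind,
                "n_nodes": n,
                "n_edges": m,
                "edge_density": density,
                "mean_degree": 2.0 * m / n if n else np.nan,
                "transitivity": trans,
                "degree_assortativity": assort,
            }
        )
    return pd.DataFrame(rows)
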