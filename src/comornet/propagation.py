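"""Random walk with restart on multiplex-heterogeneous networks (RWR-MH).

A walker moves on replicas of the disease nodes (one per disease layer)
and of the gene nodes (one per gene layer). At a node replica the walker
either steps within the current layer along (normalized) weighted edges,
jumps to another replica of the same node, or — at nodes carrying
bipartite disease-gene links — crosses to the other network through those
links. With probability ``r`` per step the walk restarts at the seed
distribution; its stationary distribution scores every node by proximity
to the seeds.

Transition column for a source replica (v, layer l) of a multiplex with L
layers, where ``delta`` is the inter-layer and ``lambda`` the
inter-network jump probability:

* mass ``lambda`` crosses the bipartite links of v (split over the other
  multiplex's layers) when v has such links, else 0;
* of the remaining within-network mass, ``1 - delta`` steps inside layer
  l proportionally to edge weight and ``delta / (L - 1)`` goes to each
  other replica of v; a replica dangling in its layer redistributes its
  within-layer share over the other replicas (or keeps it as a self-loop
  when L = 1).

Every column of the supra-transition matrix sums to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hetnet import HetNet

__all__ = [
    "RWRParams",
    "SeedProfile",
    "TransitionMatrix",
    "RWRResult",
    "build_transition",
    "rwr",
    "prioritize",
]


@dataclass
class RWRParams:
    """Parameters of the RWR-MH walk.

    restart_r : probability of restarting at the seeds each step.
    interlayer_delta : probability of jumping between layer replicas.
    internetwork_lambda : probability of crossing bipartite links at
        nodes that have them.
    disease_tau / gene_tau : per-layer restart weights (default uniform);
        each vector is normalized to sum to its number of layers.
    """

    restart_r: float = 0.7
    interlayer_delta: float = 0.5
    internetwork_lambda: float = 0.5
    disease_tau: tuple[float, ...] | None = None
    gene_tau: tuple[float, ...] | None = None
    tol: float = 1e-10
    max_iter: int = 1000
    gene_aggregation: str = "sum"  # or "mean" over layer replicas

    def __post_init__(self) -> None:
        if not (0 < self.restart_r <= 1):
            raise ValueError("restart_r must be in (0, 1]")
        for name in ("interlayer_delta", "internetwork_lambda"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gene_aggregation not in ("sum", "mean"):
            raise ValueError("gene_aggregation must be 'sum' or 'mean'")


@dataclass
class SeedProfile:
    """Weighted disease seed set (weights normalized to sum to 1)."""

    diseases: list[str]
    label: str = ""
    weights: list[float] | None = None

    def normalized_weights(self) -> np.ndarray:
        if not self.diseases:
            raise ValueError("seed profile is empty")
        if self.weights is None:
            w = np.ones(len(self.diseases))
        else:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(self.diseases) or (w < 0).any() or w.sum() == 0:
                raise ValueError("invalid seed weights")
        return w / w.sum()


@dataclass
class TransitionMatrix:
    """Column-stochastic supra-transition matrix plus index bookkeeping.

    Supra-node order: disease replicas layer-major (layer 0 diseases,
    layer 1 diseases, ...), then gene replicas layer-major.
    """

    matrix: sp.csc_matrix
    disease_universe: list[str]
    gene_universe: list[str]
    n_disease_layers: int
    n_gene_layers: int

    @property
    def n_supra(self) -> int:
        return self.matrix.shape[0]

    @property
    def gene_offset(self) -> int:
        return self.n_disease_layers * len(self.disease_universe)

    def disease_index(self, disease: str, layer: int) -> int:
        return layer * len(self.disease_universe) + self.disease_universe.index(
            disease
        )

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()


def _layer_column_stochastic(
    edges: pd.DataFrame, index: dict[str, int], n: int
) -> sp.csc_matrix:
    """Column-normalized weighted adjacency of one layer on the universe."""
    if len(edges) == 0:
        return sp.csc_matrix((n, n))
    src = edges["source"].map(index).to_numpy()
    tgt = edges["target"].map(index).to_numpy()
    w = edges["weight"].to_numpy(dtype=float)
    adj = sp.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([tgt, src]), np.concatenate([src, tgt]))),
        shape=(n, n),
    ).tocsc()
    colsum = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    return (adj @ sp.diags(inv)).tocsc()


def build_transition(net: HetNet, params: RWRParams) -> TransitionMatrix:
    """Assemble the column-stochastic supra-transition matrix of a HetNet."""
    d_univ, g_univ = net.disease_universe, net.gene_universe
    nd, ng = len(d_univ), len(g_univ)
    ld, lg = len(net.disease_layers), len(net.gene_layers)
    d_idx = {d: i for i, d in enumerate(d_univ)}
    g_idx = {g: i for i, g in enumerate(g_univ)}
    delta, lam = params.interlayer_delta, params.internetwork_lambda

    d_walk = [_layer_column_stochastic(sp_.edges, d_idx, nd) for sp_ in net.disease_layers]
    g_walk = [_layer_column_stochastic(sp_.edges, g_idx, ng) for sp_ in net.gene_layers]

    # bipartite crossing kernels, column-normalized by score
    bip = net.bipartite
    if len(bip):
        di = bip["disease"].map(d_idx).to_numpy()
        gi = bip["gene"].map(g_idx).to_numpy()
        w = bip["score"].to_numpy(dtype=float)
        b_gd = sp.coo_matrix((w, (gi, di)), shape=(ng, nd)).tocsc()  # disease -> gene
        col = np.asarray(b_gd.sum(axis=0)).ravel()
        b_gd = (b_gd @ sp.diags(np.divide(1.0, col, out=np.zeros_like(col), where=col > 0))).tocsc()
        b_dg = sp.coo_matrix((w, (di, gi)), shape=(nd, ng)).tocsc()  # gene -> disease
        col = np.asarray(b_dg.sum(axis=0)).ravel()
        b_dg = (b_dg @ sp.diags(np.divide(1.0, col, out=np.zeros_like(col), where=col > 0))).tocsc()
        d_has_bip = np.asarray(sp.coo_matrix((w, (gi, di)), shape=(ng, nd)).sum(axis=0)).ravel() > 0
        g_has_bip = np.asarray(sp.coo_matrix((w, (di, gi)), shape=(nd, ng)).sum(axis=0)).ravel() > 0
    else:
        b_gd = sp.csc_matrix((ng, nd))
        b_dg = sp.csc_matrix((nd, ng))
        d_has_bip = np.zeros(nd, dtype=bool)
        g_has_bip = np.zeros(ng, dtype=bool)

    def _multiplex_blocks(walks, has_bip, n, n_layers):
        """Within-multiplex blocks: walks[l] per layer + replica jumps."""
        wn = np.where(has_bip, 1.0 - lam, 1.0)  # within-network mass
        blocks = [[None] * n_layers for _ in range(n_layers)]
        isolated_everywhere = np.ones(n, dtype=bool)
        for l, wk in enumerate(walks):
            dangling = np.asarray(wk.sum(axis=0)).ravel() == 0
            isolated_everywhere &= dangling
            if n_layers == 1:
                blocks[0][0] = (
                    wk @ sp.diags(wn * ~dangling) + sp.diags(wn * dangling)
                ).tocsc()
            else:
                blocks[l][l] = (wk @ sp.diags(wn * (1.0 - delta) * ~dangling)).tocsc()
                jump = wn * np.where(dangling, 1.0, delta) / (n_layers - 1)
                for l2 in range(n_layers):
                    if l2 != l:
                        blocks[l2][l] = sp.diags(jump).tocsc()
        return blocks, wn, isolated_everywhere

    d_blocks, d_wn, d_iso = _multiplex_blocks(d_walk, d_has_bip, nd, ld)
    g_blocks, g_wn, g_iso = _multiplex_blocks(g_walk, g_has_bip, ng, lg)
    if (d_iso & ~d_has_bip).any() or (g_iso & ~g_has_bip).any():
        warnings.warn(
            "nodes isolated in every layer without bipartite links; "
            "their replicas exchange mass only among themselves"
        )

    # cross-network blocks: disease column -> gene rows and vice versa
    dg_block = (b_gd @ sp.diags(lam * d_has_bip)).tocsc()  # per (gene layer, disease layer)
    gd_block = (b_dg @ sp.diags(lam * g_has_bip)).tocsc()

    n_blocks = ld + lg
    grid: list[list] = [[None] * n_blocks for _ in range(n_blocks)]
    for l in range(ld):
        for l2 in range(ld):
            grid[l2][l] = d_blocks[l2][l]
        for l2 in range(lg):
            grid[ld + l2][l] = dg_block / lg
    for l in range(lg):
        for l2 in range(lg):
            grid[ld + l2][ld + l] = g_blocks[l2][l]
        for l2 in range(ld):
            grid[l2][ld + l] = gd_block / ld
    matrix = sp.bmat(grid, format="csc")
    return TransitionMatrix(matrix, list(d_univ), list(g_univ), ld, lg)


# ----------------------------------------------------------------------
@dataclass
class RWRResult:
    """Stationary probabilities of an RWR-MH run.

    ``probabilities`` covers every supra node (replica); ``gene_scores``
    aggregates each gene over its layer replicas; ``gene_ranks`` is the
    dense 1-based ranking by decreasing score, ties broken by gene id.
    """

    probabilities: np.ndarray
    gene_scores: pd.Series
    gene_ranks: pd.Series
    converged: bool
    n_iter: int
    label: str = ""
    disease_scores: pd.Series = field(default_factory=pd.Series)

    def top_genes(self, k: int) -> list[str]:
        return list(self.gene_ranks.sort_values().index[:k])


def _rank_descending(scores: pd.Series) -> pd.Series:
    """Dense 1-based ranks, highest score first, ties by id."""
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order), name="rank"
    ).reindex(scores.index)


def rwr(
    transition: TransitionMatrix, seeds: SeedProfile, params: RWRParams
) -> RWRResult:
    """Power-iterate ``p <- (1 - r) T p + r p0`` to the stationary vector.

    The restart vector ``p0`` spreads each seed disease's weight over its
    layer replicas according to the per-layer restart weights tau.
    """
    nd = len(transition.disease_universe)
    ld = transition.n_disease_layers
    w = seeds.normalized_weights()
    tau = (
        np.asarray(params.disease_tau, dtype=float)
        if params.disease_tau is not None
        else np.ones(ld)
    )
    if len(tau) != ld or (tau < 0).any() or tau.sum() == 0:
        raise ValueError("disease_tau must be nonnegative, one entry per layer")
    tau = tau / tau.sum()
    p0 = np.zeros(transition.n_supra)
    d_pos = {d: i for i, d in enumerate(transition.disease_universe)}
    for d, wd in zip(seeds.diseases, w):
        if d not in d_pos:
            raise ValueError(f"seed disease {d!r} not in disease universe")
        for l in range(ld):
            p0[l * nd + d_pos[d]] += wd * tau[l]

    r = params.restart_r
    T = transition.matrix
    p = p0.copy()
    converged = False
    n_iter = 0
    if r < 1.0:
        for n_iter in range(1, params.max_iter + 1):
            p_new = (1.0 - r) * (T @ p) + r * p0
            if np.abs(p_new - p).sum() < params.tol:
                p = p_new
                converged = True
                break
            p = p_new
        else:
            warnings.warn(f"RWR did not converge in {params.max_iter} iterations")
    else:
        converged = True

    ng = len(transition.gene_universe)
    off = transition.gene_offset
    gmat = p[off:].reshape(transition.n_gene_layers, ng)
    gvals = gmat.sum(axis=0)
    if params.gene_aggregation == "mean":
        gvals = gvals / transition.n_gene_layers
    gene_scores = pd.Series(gvals, index=pd.Index(transition.gene_universe), name="P")
    dmat = p[:off].reshape(ld, nd)
    disease_scores = pd.Series(
        dmat.sum(axis=0), index=pd.Index(transition.disease_universe)
    )
    return RWRResult(
        probabilities=p,
        gene_scores=gene_scores,
        gene_ranks=_rank_descending(gene_scores),
        converged=converged,
        n_iter=n_iter,
        label=seeds.label,
        disease_scores=disease_scores,
    )


# ----------------------------------------------------------------------
def prioritize(
    res_a: RWRResult, res_b: RWRResult, top_n: int = 500
) -> pd.DataFrame:
    """Rank-difference prioritization of profile A against profile B.

    Restricted to the ``top_n`` genes of A by probability, each gene gets
    ``G = P * |dR|`` where ``dR = rank_B - rank_A`` (positive when the
    gene ranks better under A). Genes ranking worse under A than under B
    are retained but flagged (``better_in_a`` False). Sorted by
    decreasing G.
    """
    if list(res_a.gene_scores.index) != list(res_b.gene_scores.index):
        raise ValueError("gene universes of the two results differ")
    top = res_a.gene_ranks[res_a.gene_ranks <= top_n].index
    delta = (res_b.gene_ranks[top] - res_a.gene_ranks[top]).astype(int)
    out = pd.DataFrame(
        {
            "gene": top,
            "P": res_a.gene_scores[top].to_numpy(),
            "rank_a": res_a.gene_ranks[top].to_numpy(),
            "rank_b": res_b.gene_ranks[top].to_numpy(),
            "delta_rank": delta.to_numpy(),
            "score_G": res_a.gene_scores[top].to_numpy() * np.abs(delta.to_numpy()),
            "better_in_a": (delta >= 0).to_numpy(),
        }
    )
    return out.sort_values(
        ["score_G", "gene"], ascending=[False, True], ignore_index=True
    )
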