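"""Synthetic cohorts, gene layers and signatures with planted structure.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so the full chain — cohort ->
comorbidity network -> clustering -> subtype profiles -> heterogeneous
network -> propagation -> enrichment — is testable without any external
download. Planted structure (disease clusters, subtype-discriminative
marker diseases, network-local gene modules, shifted signature genes) is
returned as an explicit ground truth object so recovery can be scored.

The generative model, briefly: each disease gets a log-uniform base
prevalence (mimicking the heavy-tailed prevalence of aggregated diagnosis
codes) and belongs to exactly one of ``n_clusters`` disease clusters.
Each patient samples one cluster (or two, with configurable probability)
and the occurrence log-odds of diseases in the patient's clusters are
raised by ``log(within_cluster_odds)``; subtype marker diseases get an
additional signed ``log(marker_odds)`` shift depending on the patient's
subtype (A vs B). Gene layers are preferential-attachment graphs over a
shared gene universe; per-cluster gene modules are breadth-first
neighborhoods of random anchor genes in the union graph, giving the
bipartite disease-gene map a guilt-by-association texture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, logit

from .cohort import DiagnosisMatrix
from .hetnet import LayerSpec

__all__ = [
    "GeneLayerSpec",
    "SynthConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_gene_layers",
    "generate_bipartite",
    "generate_phenolayer",
    "generate_signature",
    "generate_all",
]

AGE_GROUPS = ("40-59", "60-79", "80+")


@dataclass(frozen=True)
class GeneLayerSpec:
    name: str
    mean_degree: int = 4
    weighted: bool = False


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults describe a mid-sized cohort with pronounced planted
    structure: 5,000 patients over 120 diseases in 6 clusters, strong
    within-cluster co-occurrence (odds x6), 10 subtype marker diseases at
    odds x3, an 800-gene universe in 4 layers, 8 genes per disease with
    90% module locality, and a planted signature shift of 3 SD.
    """

    n_patients: int = 5000
    n_diseases: int = 120
    n_clusters: int = 6
    base_prevalence_range: tuple[float, float] = (0.01, 0.2)
    within_cluster_odds: float = 6.0
    n_subtype_markers: int = 10
    marker_odds: float = 3.0
    n_genes: int = 800
    gene_layers: tuple[GeneLayerSpec, ...] = (
        GeneLayerSpec("pathway", 4, True),
        GeneLayerSpec("ppi", 4, False),
        GeneLayerSpec("go_bp", 4, False),
        GeneLayerSpec("go_cc", 4, False),
    )
    genes_per_disease: int = 8
    module_locality: float = 0.9
    phenolayer_concordance: float = 0.5
    signature_shift: float = 3.0
    seed: int = 0
    # cluster-membership texture: 1 cluster with prob 0.7, else 2
    p_two_clusters: float = 0.3
    covariate_odds: float = 2.0  # age/sex bias on two designated clusters

    def __post_init__(self) -> None:
        lo, hi = self.base_prevalence_range
        if not (0 < lo <= hi < 1):
            raise ValueError("base_prevalence_range must satisfy 0 < lo <= hi < 1")
        if self.within_cluster_odds < 1 or self.marker_odds < 1:
            raise ValueError("odds multipliers must be >= 1")
        if self.n_clusters > self.n_diseases:
            raise ValueError("n_clusters must not exceed n_diseases")
        if not (0 <= self.module_locality <= 1):
            raise ValueError("module_locality must be in [0, 1]")
        if not (0 <= self.phenolayer_concordance <= 1):
            raise ValueError("phenolayer_concordance must be in [0, 1]")
        if not (0 <= self.p_two_clusters <= 1):
            raise ValueError("p_two_clusters must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic RNG stream per generator stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    cluster_of_disease: dict[str, int]
    subtype_marker_sign: dict[str, int]  # +1 (subtype A), -1 (B), 0
    gene_module_of_cluster: dict[int, set[str]] = field(default_factory=dict)
    planted_signature_genes: set[str] = field(default_factory=set)
    genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cluster_of_disease": self.cluster_of_disease,
            "subtype_marker_sign": self.subtype_marker_sign,
            "gene_module_of_cluster": {
                str(k): sorted(v) for k, v in self.gene_module_of_cluster.items()
            },
            "planted_signature_genes": sorted(self.planted_signature_genes),
            "genes": self.genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            d["cluster_of_disease"],
            {k: int(v) for k, v in d["subtype_marker_sign"].items()},
            {int(k): set(v) for k, v in d["gene_module_of_cluster"].items()},
            set(d["planted_signature_genes"]),
            d["genes"],
        )


# ----------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------
def generate_cohort(cfg: SynthConfig) -> tuple[DiagnosisMatrix, GroundTruth]:
    """Binary patient x disease matrix with planted clusters and markers.

    Patients get a balanced A/B subtype, an age group and a sex; two
    designated clusters have their membership odds biased by age (oldest
    group) and sex (female), which is what makes covariate-stratified
    cluster-similarity contrasts non-trivial. Marker diseases are drawn
    from cluster 0 (+1, over-represented in subtype A) and cluster 1 (-1,
    over-represented in subtype B).
    """
    rng = cfg.rng(1)
    diseases = [f"D{i:03d}" for i in range(cfg.n_diseases)]
    patients = [f"P{i:05d}" for i in range(cfg.n_patients)]

    lo, hi = cfg.base_prevalence_range
    prevalence = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_diseases))

    cluster_of = {
        d: int(c)
        for d, c in zip(
            diseases,
            np.concatenate(
                [
                    np.full(len(chunk), k)
                    for k, chunk in enumerate(
                        np.array_split(np.arange(cfg.n_diseases), cfg.n_clusters)
                    )
                ]
            ),
        )
    }
    cluster_arr = np.array([cluster_of[d] for d in diseases])

    # subtype markers: half +1 from cluster 0, half -1 from cluster 1
    signs = dict.fromkeys(diseases, 0)
    n_plus = cfg.n_subtype_markers - cfg.n_subtype_markers // 2
    n_minus = cfg.n_subtype_markers // 2
    for cl, n_mark, sign in ((0, n_plus, 1), (1, n_minus, -1)):
        pool = [d for d in diseases if cluster_of[d] == cl]
        if n_mark > len(pool):
            raise ValueError("n_subtype_markers too large for cluster size")
        for d in rng.choice(pool, size=n_mark, replace=False):
            signs[str(d)] = sign
    sign_arr = np.array([signs[d] for d in diseases])

    subtype = np.where(rng.random(cfg.n_patients) < 0.5, "A", "B")
    sex = np.where(rng.random(cfg.n_patients) < 0.5, "F", "M")
    age = rng.choice(AGE_GROUPS, size=cfg.n_patients, p=(0.3, 0.5, 0.2))

    # patient cluster membership (1 cluster, or 2 with p_two_clusters),
    # with covariate-biased odds on two designated clusters
    age_cluster = min(2, cfg.n_clusters - 1)
    sex_cluster = min(3, cfg.n_clusters - 1)
    weights = np.ones((cfg.n_patients, cfg.n_clusters))
    weights[age == "80+", age_cluster] *= cfg.covariate_odds
    weights[sex == "F", sex_cluster] *= cfg.covariate_odds
    weights /= weights.sum(axis=1, keepdims=True)
    member = np.zeros((cfg.n_patients, cfg.n_clusters), dtype=bool)
    two = rng.random(cfg.n_patients) < cfg.p_two_clusters
    u = rng.random((cfg.n_patients, 2))
    cum = np.cumsum(weights, axis=1)
    first = (u[:, [0]] < cum).argmax(axis=1)
    member[np.arange(cfg.n_patients), first] = True
    if cfg.n_clusters > 1:
        # second cluster drawn from the renormalized remainder
        w2 = weights.copy()
        w2[np.arange(cfg.n_patients), first] = 0.0
        w2 /= w2.sum(axis=1, keepdims=True)
        second = (u[:, [1]] < np.cumsum(w2, axis=1)).argmax(axis=1)
        member[two, second[two]] = True

    base_logit = logit(prevalence)
    in_cluster = member[:, cluster_arr]  # patients x diseases
    logits = (
        base_logit[None, :]
        + np.log(cfg.within_cluster_odds) * in_cluster
        + np.log(cfg.marker_odds)
        * np.where(subtype == "A", 1.0, -1.0)[:, None]
        * sign_arr[None, :]
    )
    probs = expit(logits)
    if np.all(probs == 0):
        raise ValueError("expected disease count per patient is zero")
    occ = (rng.random((cfg.n_patients, cfg.n_diseases)) < probs).astype(np.int8)

    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "subtype": subtype}, index=pd.Index(patients)
    )
    dm = DiagnosisMatrix(patients, diseases, sp.csr_matrix(occ), covariates)
    truth = GroundTruth(cluster_of, signs)
    return dm, truth


# ----------------------------------------------------------------------
# gene layers and modules
# ----------------------------------------------------------------------
def generate_gene_layers(
    cfg: SynthConfig, truth: GroundTruth
) -> list[LayerSpec]:
    """Modular scale-free gene layers over a shared universe.

    Per-cluster gene modules are disjoint random subsets of size
    ``n_genes // n_clusters`` assigned up front (leftover genes belong to
    no module). Each layer is the union of a preferential-attachment
    subgraph inside every module and a sparser preferential-attachment
    background over the whole universe, so modules are genuinely
    network-local (guilt-by-association structure the propagation relies
    on) while degrees stay heavy-tailed and the total mean degree matches
    the layer's ``mean_degree``. Weighted layers carry integer weights in
    [1, 5] emulating evidence-resource counts. The module map and the
    planted signature gene set (the module of cluster 0) are stored on
    ``truth``.
    """
    rng = cfg.rng(2)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    truth.genes = genes

    module_size = cfg.n_genes // cfg.n_clusters
    order = rng.permutation(cfg.n_genes)
    modules = {
        cl: {genes[i] for i in order[cl * module_size : (cl + 1) * module_size]}
        for cl in range(cfg.n_clusters)
    }
    truth.gene_module_of_cluster = modules
    truth.planted_signature_genes = set(modules[0])

    layers: list[LayerSpec] = []
    for spec in cfg.gene_layers:
        # split the degree budget between within-module and background
        # attachment; total mean degree ~= 2 * (m_in + m_out) ~= mean_degree
        m_in = max(1, round(spec.mean_degree / 4))
        m_out = max(0, round(spec.mean_degree / 2) - m_in)
        pairs: list[tuple[str, str]] = []
        for cl in range(cfg.n_clusters):
            members = sorted(modules[cl])
            sub = nx.barabasi_albert_graph(
                len(members), m_in, seed=int(rng.integers(2**31))
            )
            perm = rng.permutation(len(members))
            pairs += [(members[perm[u]], members[perm[v]]) for u, v in sub.edges()]
        if m_out > 0:
            bg = nx.barabasi_albert_graph(
                cfg.n_genes, m_out, seed=int(rng.integers(2**31))
            )
            perm = rng.permutation(cfg.n_genes)
            pairs += [(genes[perm[u]], genes[perm[v]]) for u, v in bg.edges()]
        edges = pd.DataFrame(pairs, columns=["source", "target"])
        if spec.weighted:
            edges["weight"] = rng.integers(1, 6, size=len(edges)).astype(float)
        else:
            edges["weight"] = 1.0
        layers.append(LayerSpec(spec.name, "gene", edges, spec.weighted))
    return layers


# ----------------------------------------------------------------------
# bipartite disease-gene associations
# ----------------------------------------------------------------------
def generate_bipartite(cfg: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Disease-gene association table with uniform confidence scores.

    Each disease receives ``genes_per_disease`` distinct genes; with
    probability ``module_locality`` a gene comes from the disease's
    cluster module, otherwise uniformly from the whole universe.
    Confidence scores are uniform on [0.05, 1.0] so a strict confidence
    filter removes a predictable fraction.
    """
    if not truth.gene_module_of_cluster:
        raise ValueError("gene modules missing: run generate_gene_layers first")
    rng = cfg.rng(3)
    genes = np.asarray(truth.genes, dtype=object)
    rows = []
    for disease, cl in truth.cluster_of_disease.items():
        module = np.asarray(sorted(truth.gene_module_of_cluster[cl]), dtype=object)
        chosen: set[str] = set()
        guard = 0
        while len(chosen) < cfg.genes_per_disease and guard < 1000:
            guard += 1
            if rng.random() < cfg.module_locality:
                g = str(rng.choice(module))
            else:
                g = str(rng.choice(genes))
            chosen.add(g)
        for g in sorted(chosen):
            rows.append((disease, g, float(rng.uniform(0.05, 1.0))))
    return pd.DataFrame(rows, columns=["disease", "gene", "score"])


# ----------------------------------------------------------------------
# phenotype-similarity disease layer
# ----------------------------------------------------------------------
def generate_phenolayer(
    truth: GroundTruth, concordance: float, seed: int = 0
) -> pd.DataFrame:
    """Disease edge list partially concordant with the planted clusters.

    Same-cluster pairs connect with probability ``concordance``,
    cross-cluster pairs with ``concordance / 10``.
    """
    if not (0 <= concordance <= 1):
        raise ValueError("concordance must be in [0, 1]")
    rng = np.random.default_rng([seed, 4])
    diseases = sorted(truth.cluster_of_disease)
    rows = []
    for i, a in enumerate(diseases):
        for b in diseases[i + 1 :]:
            same = truth.cluster_of_disease[a] == truth.cluster_of_disease[b]
            p = concordance if same else concordance / 10.0
            if rng.random() < p:
                rows.append((a, b, 1.0))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


# ----------------------------------------------------------------------
# ranked transcriptomic signature
# ----------------------------------------------------------------------
def generate_signature(
    truth: GroundTruth, shift: float, seed: int = 0
) -> pd.DataFrame:
    """Ranked signature: standard-normal t-statistics, planted genes
    shifted by ``+shift``, sorted by decreasing t."""
    if not truth.genes:
        raise ValueError("gene universe missing: run generate_gene_layers first")
    rng = np.random.default_rng([seed, 5])
    t = rng.standard_normal(len(truth.genes))
    planted = np.array([g in truth.planted_signature_genes for g in truth.genes])
    t = t + shift * planted
    df = pd.DataFrame({"gene": truth.genes, "t": t})
    return df.sort_values("t", ascending=False, ignore_index=True)


# ----------------------------------------------------------------------
@dataclass
class SyntheticDataset:
    cohort: DiagnosisMatrix
    truth: GroundTruth
    gene_layers: list[LayerSpec]
    bipartite: pd.DataFrame
    phenolayer: pd.DataFrame
    signature: pd.DataFrame


def generate_all(cfg: SynthConfig) -> SyntheticDataset:
    """Run every generator stage under one config (one shared seed)."""
    dm, truth = generate_cohort(cfg)
    layers = generate_gene_layers(cfg, truth)
    bip = generate_bipartite(cfg, truth)
    pheno = generate_phenolayer(truth, cfg.phenolayer_concordance, seed=cfg.seed)
    sig = generate_signature(truth, cfg.signature_shift, seed=cfg.seed)
    return SyntheticDataset(dm, truth, layers, bip, pheno, sig)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write all generated inputs as TSV/JSON into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.cohort.write(out / "cohort.tsv", out / "covariates.tsv")
    for sp_ in ds.gene_layers:
        sp_.edges.to_csv(out / f"gene_layer_{sp_.name}.tsv", sep="\t", index=False)
    ds.bipartite.to_csv(out / "disease_gene.tsv", sep="\t", index=False)
    ds.phenolayer.to_csv(out / "phenolayer.tsv", sep="\t", index=False)
    ds.signature.to_csv(out / "signature.tsv", sep="\t", index=False)
    ds.truth.to_json(out / "ground_truth.json")
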