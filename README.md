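# comornet

Comorbidity-network medicine in Python: from routine diagnosis data to
network-based candidate genes for disease subtypes.

Many chronic syndromes — heart failure with preserved ejection fraction
is the motivating example — are driven less by a single lesion than by a
patient's accumulated comorbidities. `comornet` implements the analysis
chain that turns that observation into gene-level hypotheses:

1. **Comorbidity network.** From a binary patient × diagnosis matrix,
   every disease pair is tested with the two-sided Fisher exact test;
   edges with Benjamini–Hochberg q < α and positive φ correlation
   (Pearson correlation of the binary indicators,
   φ = (ad−bc)/√((a+b)(c+d)(a+c)(b+d))) form an undirected weighted
   network. Weights are φ rescaled by per-disease mean correlation,
   W_ij = φ_ij/√(m̄_i·m̄_j); graph distances use S = max(W) − W.
2. **Disease clusters and subtype profiles.** Weighted-modularity
   (Leiden/Louvain) clustering; patient-to-cluster Jaccard similarity
   with Wilcoxon cohort contrasts; MCA-based covariate variance
   attribution; and an elastic-net classifier with forward selection
   that yields a signed comorbidity profile per subtype.
3. **Heterogeneous network and propagation.** The disease network plus a
   phenotype-similarity layer, a multi-layer gene network (pathway, PPI,
   ontology), and confidence-filtered disease–gene links form a
   multiplex-heterogeneous network. Random walk with restart (RWR-MH)
   propagates a comorbidity profile's seed mass to a stationary
   distribution p = (1−r)·T·p + r·p₀, ranking every gene.
4. **Evaluation and prioritization.** Leave-one-out disease–gene
   recovery (AUROC, AUC-PR, rank ratio) against rewired-network and
   random-seed nulls; subtype-specific gene prioritization
   G_i = P_i·|ΔR_i|; and pre-ranked GSEA of predicted genes in an
   external transcriptomic signature.

A synthetic-data generator with planted clusters, subtype markers, gene
modules and signature shifts makes the whole chain runnable and testable
without access to hospital records or licensed databases. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import comornet as cn

# synthetic cohort: 2,500 patients, 40 diseases in 4 planted clusters
cfg = cn.SynthConfig(n_patients=2500, n_diseases=40, n_clusters=4,
                     n_genes=200, genes_per_disease=6, seed=11)
ds = cn.generate_all(cfg)

net = cn.build_network(cn.pairwise_association(ds.cohort), alpha=1e-4)
cs = cn.detect_clusters(net, seed=0)
print(f"{net.n_nodes} diseases, {net.n_edges} edges, "
      f"{cs.n_clusters} clusters (Q={cs.quality:.2f})")

hn = cn.assemble(
    [cn.disease_layer_from_network(net),
     cn.LayerSpec("phenotype", "disease", ds.phenolayer)],
    ds.gene_layers,
    cn.filter_bipartite(ds.bipartite, 0.29),
)
params = cn.RWRParams()
loo = cn.loo_recovery(hn, params)
print(f"LOO recovery over {len(loo)} diseases: "
      f"median AUROC {loo['auroc'].median():.2f}, "
      f"median rank ratio {loo['rank_ratio'].median():.3f}")

seeds = [d for d, c in ds.truth.cluster_of_disease.items() if c == 0]
res = cn.rwr(cn.build_transition(hn, params),
             cn.SeedProfile(seeds, label="cluster0"), params)
enr = cn.gsea_preranked(ds.signature, set(res.top_genes(100)),
                        n_perm=2000, seed=0)
print(f"top-100 predicted genes in the planted signature: "
      f"ES={enr.es:.2f}, p={enr.p_value:.1e}")
```

prints

```
40 diseases, 83 edges, 4 clusters (Q=0.70)
LOO recovery over 40 diseases: median AUROC 0.77, median rank ratio 0.211
top-100 predicted genes in the planted signature: ES=0.66, p=5.0e-04
```

The four planted clusters are recovered exactly (modularity 0.70); after
deleting each disease's own gene links, propagation still ranks the
held-out genes far above chance (median AUROC 0.77 versus 0.5); and the
genes predicted from the cluster-0 comorbidity profile are strongly
enriched at the top of the signature whose shift was planted in that
cluster's gene module (the permutation floor of 2,000 draws is
1/2001 ≈ 5·10⁻⁴).

A thin CLI wraps the same functions: `comornet synth`, `comornet net
build|cluster|centrality`, `comornet profiles mca|select`, `comornet
hetnet stats`, `comornet rwr run`, `comornet eval loo|gsea` — run any of
them with `--help`.

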