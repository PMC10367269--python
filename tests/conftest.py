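"""Shared fixtures: one mid-sized synthetic dataset reused across modules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import comornet as cn
from comornet.cohort import DiagnosisMatrix


@pytest.fixture(scope="session")
def small_cfg() -> cn.SynthConfig:
    return cn.SynthConfig(
        n_patients=2500,
        n_diseases=40,
        n_clusters=4,
        n_genes=200,
        genes_per_disease=6,
        module_locality=0.9,
        seed=11,
    )


@pytest.fixture(scope="session")
def dataset(small_cfg):
    return cn.generate_all(small_cfg)


@pytest.fixture(scope="session")
def disease_network(dataset):
    assoc = cn.pairwise_association(dataset.cohort)
    return cn.build_network(assoc, alpha=1e-4)


@pytest.fixture(scope="session")
def clusters(disease_network):
    return cn.detect_clusters(disease_network, seed=0)


@pytest.fixture(scope="session")
def hetnet_full(dataset, disease_network):
    dlayer = cn.disease_layer_from_network(disease_network)
    pheno = cn.LayerSpec("phenotype", "disease", dataset.phenolayer)
    bip = cn.filter_bipartite(dataset.bipartite, 0.29)
    return cn.assemble([dlayer, pheno], dataset.gene_layers, bip)


def make_dm(occ: np.ndarray, covariates: pd.DataFrame | None = None,
            diseases: list[str] | None = None) -> DiagnosisMatrix:
    """Build a DiagnosisMatrix from a dense 0/1 array."""
    occ = np.asarray(occ, dtype=np.int8)
    patients = [f"P{i:04d}" for i in range(occ.shape[0])]
    if diseases is None:
        diseases = [f"D{j:03d}" for j in range(occ.shape[1])]
    cov = covariates if covariates is not None else pd.DataFrame(index=patients)
    if covariates is not None:
        cov = covariates.set_axis(patients)
    return DiagnosisMatrix(patients, diseases, sp.csr_matrix(occ), cov)
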