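"""Patient-to-disease-cluster similarity and cohort contrasts.

Each patient's comorbidity set is compared to each disease cluster (DC)
by Jaccard index; cohorts of patients (age strata, sexes, subtypes) are
then contrasted per cluster with a two-sided Wilcoxon rank-sum test. For
visualization-friendly output the log-transformed p-value is signed by
the direction of the location shift (positive = first cohort more similar
to the cluster).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DiagnosisMatrix
from .comorbidity import DiseaseClusterSet, bh_adjust

__all__ = ["patient_dc_jaccard", "contrast_cohorts"]


def patient_dc_jaccard(
    dm: DiagnosisMatrix,
    clusters: DiseaseClusterSet,
    restrict_to_network: bool = True,
) -> pd.DataFrame:
    """Jaccard index of every patient's disease set with every cluster.

    ``J(patient, DC) = |P & DC| / |P | DC|``. By default the patient's
    disease set is restricted to diseases covered by the cluster
    partition (i.e. network diseases); patients left with no diseases get
    an all-zero row and are listed in ``result.attrs['zero_patients']``.
    """
    cluster_ids = sorted(set(clusters.membership.values()))
    d_index = {d: j for j, d in enumerate(dm.diseases)}
    clustered = [d for d in clusters.membership if d in d_index]
    X = dm.occurrence.tocsc()
    if restrict_to_network:
        patient_sizes = np.asarray(
            X[:, [d_index[d] for d in clustered]].sum(axis=1)
        ).ravel()
    else:
        patient_sizes = np.asarray(X.sum(axis=1)).ravel()
    out = np.zeros((dm.n_patients, len(cluster_ids)))
    for k, cid in enumerate(cluster_ids):
        members = [d for d in clustered if clusters.membership[d] == cid]
        cols = [d_index[d] for d in members]
        inter = np.asarray(X[:, cols].sum(axis=1)).ravel()
        union = patient_sizes + len(members) - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, k] = np.where(union > 0, inter / union, 0.0)
    df = pd.DataFrame(out, index=pd.Index(dm.patients), columns=cluster_ids)
    df.attrs["zero_patients"] = [
        p for p, s in zip(dm.patients, patient_sizes) if s == 0
    ]
    return df


def contrast_cohorts(
    jmat: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate: str,
    level_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-cluster Wilcoxon rank-sum contrasts between patient cohorts.

    For each (cohort_a, cohort_b) pair of covariate levels and each
    cluster, the two-sided rank-sum test compares the Jaccard similarity
    values; the sign of the contrast is the sign of the rank-based
    location shift (positive when cohort_a values tend to be larger, the
    sign of the Hodges-Lehmann shift estimate). ``signed_logp`` is
    ``-log10(p)`` carrying that sign; BH-adjusted p-values are reported
    per contrast across clusters.
    """
    cov = covariates.loc[jmat.index, covariate]
    rows = []
    for lev_a, lev_b in level_pairs:
        mask_a = (cov == lev_a).to_numpy(dtype=bool)
        mask_b = (cov == lev_b).to_numpy(dtype=bool)
        if mask_a.sum() == 0 or mask_b.sum() == 0:
            raise ValueError(f"empty cohort in contrast {lev_a!r} vs {lev_b!r}")
        for cid in jmat.columns:
            x = jmat.loc[mask_a, cid].to_numpy()
            y = jmat.loc[mask_b, cid].to_numpy()
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                u, p, sign = len(x) * len(y) / 2.0, 1.0, 0
            else:
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                u, p = float(res.statistic), float(res.pvalue)
                # sign of U - n1 n2 / 2 == sign of the HL location shift
                sign = int(np.sign(u - len(x) * len(y) / 2.0))
            rows.append(
                {
                    "cluster": cid,
                    "cohort_a": lev_a,
                    "cohort_b": lev_b,
                    "statistic": u,
                    "p_value": p,
                    "signed_logp": -np.log10(max(p, np.finfo(float).tiny)) * sign,
                }
            )
    out = pd.DataFrame(rows)
    out["q_bh"] = np.nan
    for (lev_a, lev_b) in level_pairs:
        m = (out["cohort_a"] == lev_a) & (out["cohort_b"] == lev_b)
        out.loc[m, "q_bh"] = bh_adjust(out.loc[m, "p_value"].to_numpy())
    return out
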