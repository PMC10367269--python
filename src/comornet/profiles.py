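"""Covariate variance attribution (MCA) and subtype comorbidity profiles.

Multiple correspondence analysis decomposes the binary comorbidity matrix
(coded as a two-category indicator: presence and absence of each disease)
into orthogonal dimensions; regressing each dimension on a clinical
covariate and summing the inertia of the significantly associated
dimensions estimates the comorbidity variance tied to that covariate.

The subtype comorbidity profile comes from a regularized (elastic-net)
logistic classifier of the two subtype labels on the disease indicators,
followed by forward selection over the nonzero-coefficient diseases with
an L1 model; the sign of a selected disease's coefficient assigns it to
one subtype or the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .cohort import DiagnosisMatrix

__all__ = [
    "McaResult",
    "run_mca",
    "CovariateVariance",
    "variance_attribution",
    "fit_profile_classifier",
    "ComorbidityProfile",
    "forward_select",
]


# ----------------------------------------------------------------------
# multiple correspondence analysis
# ----------------------------------------------------------------------
@dataclass
class McaResult:
    """Patient coordinates and inertia decomposition of the MCA."""

    coordinates: np.ndarray  # patients x kept dimensions (principal coords)
    dim_inertia: np.ndarray  # percentage of total inertia, all nonzero dims
    total_inertia: float
    dropped_diseases: list[str] = field(default_factory=list)

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


def run_mca(dm: DiagnosisMatrix, n_dims: int | None = None) -> McaResult:
    """Correspondence analysis of the complete disjunctive indicator.

    Each disease contributes two indicator columns (present / absent);
    the SVD of the standardized residual matrix of that table yields
    patient principal coordinates and per-dimension inertia percentages.
    Constant disease columns carry no inertia and are dropped with a
    warning. ``n_dims`` caps the number of returned coordinate columns
    (default ``min(50, rank)``).
    """
    if dm.n_diseases < 2:
        raise ValueError("MCA needs at least 2 diseases")
    X = np.asarray(dm.occurrence.todense(), dtype=float)
    prev = X.mean(axis=0)
    constant = (prev == 0) | (prev == 1)
    dropped = [d for d, c in zip(dm.diseases, constant) if c]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant disease column(s)")
        X = X[:, ~constant]
    Z = np.hstack([X, 1.0 - X])  # two categories per disease
    G = Z / Z.sum()
    r = G.sum(axis=1)
    c = G.sum(axis=0)
    resid = (G - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    total = float((s**2).sum())
    keep = s**2 > 1e-12 * max(total, 1.0)
    s, u = s[keep], u[:, keep]
    if n_dims is None:
        n_dims = min(50, len(s))
    n_dims = min(n_dims, len(s))
    coords = (u[:, :n_dims] * s[:n_dims]) / np.sqrt(r)[:, None]
    return McaResult(
        coordinates=coords,
        dim_inertia=100.0 * s**2 / total,
        total_inertia=total,
        dropped_diseases=dropped,
    )


@dataclass
class CovariateVariance:
    covariate: str
    explained_pct: float
    significant_dims: list[int]
    dim_pvalues: list[float] = field(default_factory=list)


def variance_attribution(
    mca: McaResult,
    dm: DiagnosisMatrix,
    covariate: str,
    p_cut: float = 0.05,
) -> CovariateVariance:
    """Sum the inertia of MCA dimensions significantly associated with a
    covariate.

    Numeric covariates use the slope test of an ordinary least-squares
    regression of the dimension coordinate on the covariate; categorical
    covariates use the equivalent one-way ANOVA F-test. A constant
    covariate explains nothing.
    """
    values = dm.covariates[covariate]
    numeric = pd.api.types.is_numeric_dtype(values)
    pvals = []
    if values.nunique(dropna=True) < 2:
        return CovariateVariance(covariate, 0.0, [], [])
    mask = values.notna().to_numpy()
    for k in range(mca.n_dims):
        y = mca.coordinates[mask, k]
        if numeric:
            res = stats.linregress(values.to_numpy(dtype=float)[mask], y)
            pvals.append(float(res.pvalue))
        else:
            groups = [y[(values[mask] == lev).to_numpy()] for lev in values.dropna().unique()]
            pvals.append(float(stats.f_oneway(*groups).pvalue))
    sig = [k for k, p in enumerate(pvals) if p < p_cut]
    explained = float(mca.dim_inertia[sig].sum()) if sig else 0.0
    return CovariateVariance(covariate, explained, sig, pvals)


# ----------------------------------------------------------------------
# classifier and forward selection
# ----------------------------------------------------------------------
def _binary_y(labels: pd.Series | np.ndarray) -> tuple[np.ndarray, list[str]]:
    labels = pd.Series(np.asarray(labels, dtype=object))
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"labels must have exactly 2 levels, got {classes}")
    y = (labels == classes[1]).to_numpy(dtype=int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 patients per class")
    return y, [str(c) for c in classes]


def fit_profile_classifier(
    dm: DiagnosisMatrix,
    labels: pd.Series | np.ndarray,
    l1_ratio: float = 0.5,
    folds: int = 5,
    seed: int = 0,
    n_penalties: int = 20,
) -> tuple[pd.Series, float, list[str]]:
    """Elastic-net logistic classifier of a two-level label.

    Cross-validated search over ``n_penalties`` log-spaced penalty
    strengths (stratified ``folds``-fold CV, AUROC scoring). Returns the
    coefficient vector of the best model (indexed by disease; positive
    coefficients point to the second class in the returned class list),
    the best mean CV AUROC, and the class order.
    """
    y, classes = _binary_y(labels)
    X = np.asarray(dm.occurrence.todense(), dtype=float)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    penalties = np.logspace(-4, 4, n_penalties)
    best_c, best_score = penalties[0], -np.inf
    for c in penalties:
        model = LogisticRegression(
            solver="saga", l1_ratio=l1_ratio, C=c, max_iter=5000,
            tol=1e-4, random_state=seed,
        )
        score = float(
            cross_val_score(model, X, y, cv=cv, scoring="roc_auc").mean()
        )
        if score > best_score:
            best_c, best_score = c, score
    final = LogisticRegression(
        solver="saga", l1_ratio=l1_ratio, C=best_c, max_iter=5000,
        tol=1e-4, random_state=seed,
    ).fit(X, y)
    coef = pd.Series(final.coef_.ravel(), index=pd.Index(dm.diseases), name="coef")
    return coef, float(best_score), classes


@dataclass
class ComorbidityProfile:
    """Subtype-discriminative comorbidity profile.

    ``assignments`` maps each selected disease to (cohort label, absolute
    coefficient); positive-coefficient diseases belong to one cohort,
    negative to the other, consistently.
    """

    assignments: dict[str, tuple[str, float]]
    model_size: int
    cv_auroc: float
    auroc_curve: dict[int, float] = field(default_factory=dict)
    classes: list[str] = field(default_factory=list)

    def diseases_for(self, label: str) -> list[str]:
        return sorted(d for d, (lab, _) in self.assignments.items() if lab == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"disease": d, "cohort": lab, "coefficient": mag}
                for d, (lab, mag) in sorted(self.assignments.items())
            ]
        )


def forward_select(
    dm: DiagnosisMatrix,
    labels: pd.Series | np.ndarray,
    ranked_features: list[str],
    step: int = 10,
    folds: int = 5,
    seed: int = 0,
    tolerance: float = 0.002,
    C: float = 1.0,
) -> ComorbidityProfile:
    """Forward selection over coefficient-ranked diseases with L1 models.

    Feature sets grow in increments of ``step`` following
    ``ranked_features`` (diseases ordered by decreasing absolute
    elastic-net coefficient). Each size is scored by stratified
    cross-validated AUROC of an L1 logistic model; the profile uses the
    smallest size whose AUROC is within ``tolerance`` of the maximum.
    The final model is refit on all patients and diseases with nonzero
    coefficients are assigned to a cohort by coefficient sign.
    """
    if not ranked_features:
        raise ValueError("ranked_features is empty")
    y, classes = _binary_y(labels)
    d_index = {d: i for i, d in enumerate(dm.diseases)}
    X_full = np.asarray(dm.occurrence.todense(), dtype=float)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sizes = list(range(step, len(ranked_features) + 1, step))
    if sizes[-1] != len(ranked_features):
        sizes.append(len(ranked_features))
    curve: dict[int, float] = {}
    for size in sizes:
        cols = [d_index[d] for d in ranked_features[:size]]
        model = LogisticRegression(
            solver="liblinear", l1_ratio=1.0, C=C, random_state=seed
        )
        curve[size] = float(
            cross_val_score(model, X_full[:, cols], y, cv=cv, scoring="roc_auc").mean()
        )
    best = max(curve.values())
    selected_size = min(s for s in sizes if curve[s] >= best - tolerance)
    cols = [d_index[d] for d in ranked_features[:selected_size]]
    final = LogisticRegression(
        solver="liblinear", l1_ratio=1.0, C=C, random_state=seed
    ).fit(X_full[:, cols], y)
    coefs = final.coef_.ravel()
    assignments = {
        ranked_features[:selected_size][k]: (
            classes[1] if coefs[k] > 0 else classes[0],
            float(abs(coefs[k])),
        )
        for k in range(selected_size)
        if coefs[k] != 0.0
    }
    return ComorbidityProfile(
        assignments=assignments,
        model_size=len(assignments),
        cv_auroc=curve[selected_size],
        auroc_curve=curve,
        classes=classes,
    )
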