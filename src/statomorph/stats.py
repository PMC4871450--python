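"""Morphometric statistics: ANOVA/Tukey on L:W, Kaiser-criterion PCA,
canonical discriminant analysis with Wilks' lambda, Rao's F, and
leave-one-out jackknife classification, plus per-species allometry
regression.

Canonical discriminant analysis (CDA) here follows the classical
formulation: with between-group SSCP matrix B and pooled within-group SSCP
matrix W, the canonical variates are the eigenvectors of W⁻¹B, scaled so
that the pooled within-group variance of each canonical score is 1.
Classification assigns an observation to the group whose centroid is
nearest in canonical space (Euclidean distance there equals Mahalanobis
distance with respect to the pooled within-group covariance), offset by
the log prior.  Wilks' Λ = Π 1/(1+λᵢ) over the eigenvalues λᵢ, tested with
Rao's F approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    InsufficientDataError,
    ParameterError,
    UndefinedSlopeError,
)

RIDGE_EPS = 1e-8  # relative ridge added to a singular pooled covariance


# --------------------------------------------------------------------------
# One-way ANOVA with Tukey-Kramer post hoc
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    group_means: pd.Series
    tukey: pd.DataFrame  # group_i, group_j, mean_diff, q_statistic, adjusted_p


def anova_oneway(values, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA with Tukey-Kramer pairwise comparisons.

    Groups may be unbalanced; the Tukey-Kramer form of the studentized
    range test handles unequal n.  A group of size one contributes nothing
    to the within-group sum of squares (and no within-group df beyond the
    usual N - k accounting).
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    N = len(values)
    if k < 2:
        raise InsufficientDataError("ANOVA needs at least 2 groups")
    if N <= k:
        raise InsufficientDataError("ANOVA needs N > k observations")

    means = np.array([values[groups == g].mean() for g in labels])
    ns = np.array([(groups == g).sum() for g in labels])
    grand = values.mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((values[groups == g] - m) ** 2).sum() for g, m in zip(labels, means)))
    df1, df2 = k - 1, N - k
    msb = ssb / df1
    msw = ssw / df2
    if msw == 0.0:
        F = 0.0 if msb == 0.0 else np.inf
    else:
        F = msb / msw
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = np.abs(diff) / se if se > 0 else np.inf
            padj = float(sps.studentized_range.sf(q, k, df2)) if np.isfinite(q) else 0.0
            rows.append((labels[i], labels[j], diff, q, min(padj, 1.0)))
    tukey = pd.DataFrame(
        rows, columns=["group_i", "group_j", "mean_diff", "q_statistic", "adjusted_p"]
    )
    return AnovaResult(
        F=float(F), df1=df1, df2=df2, p=p,
        group_means=pd.Series(means, index=labels), tukey=tukey,
    )


# --------------------------------------------------------------------------
# Kaiser-criterion PCA
# --------------------------------------------------------------------------

@dataclass
class PCASelection:
    eigenvalues: np.ndarray          # all p, non-increasing
    retained_count: int              # Kaiser criterion: eigenvalue > 1
    scores: np.ndarray               # N x retained
    loadings: np.ndarray             # p x retained (eigenvectors)
    columns: list = field(default_factory=list)
    face: str | None = None
    means: np.ndarray | None = None  # training means/sds for projecting
    sds: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new rows onto the retained components."""
        Z = (np.asarray(X, dtype=np.float64) - self.means) / self.sds
        return Z @ self.loadings


def pca_select(features, face: str | None = None) -> PCASelection:
    """PCA on the correlation matrix with Kaiser-criterion retention.

    Components whose correlation-matrix eigenvalue exceeds 1 explain more
    variance than a single standardized variable and are retained; the rest
    are dropped.  Zero-variance columns are removed with a warning before
    standardization.
    """
    if isinstance(features, pd.DataFrame):
        cols = list(features.columns)
        X = features.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        cols = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] <= 1:
        raise InsufficientDataError("PCA needs more than one observation")

    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance column(s) before PCA",
            stacklevel=2,
        )
        X = X[:, keep]
        cols = [c for c, k in zip(cols, keep) if k]
        sds = sds[keep]
    means = X.mean(axis=0)
    Z = (X - means) / sds
    corr = np.corrcoef(Z, rowvar=False)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # deterministic eigenvector sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        lead = eigvec[np.argmax(np.abs(eigvec[:, j])), j]
        if lead < 0:
            eigvec[:, j] *= -1.0
    retained = int((eigval > 1.0).sum())
    loadings = eigvec[:, :retained]
    return PCASelection(
        eigenvalues=eigval,
        retained_count=retained,
        scores=Z @ loadings,
        loadings=loadings,
        columns=cols,
        face=face,
        means=means,
        sds=sds,
    )


# --------------------------------------------------------------------------
# Canonical discriminant analysis
# --------------------------------------------------------------------------

@dataclass
class CDAModel:
    group_labels: list
    priors: np.ndarray                   # per group, sums to 1
    canonical_coefficients: np.ndarray   # p x m, m = min(p, k-1)
    group_centroids: np.ndarray          # k x m, in canonical space
    eigenvalues: np.ndarray              # m discriminant eigenvalues
    wilks_lambda: float
    rao_F: float
    df1: int
    df2: int
    p_value: float
    n_obs: int
    n_features: int


@dataclass
class ConfusionTable:
    mode: str                            # "resubstitution" or "jackknife"
    labels: list
    counts: np.ndarray                   # k x k, true x predicted
    percent_correct_per_group: np.ndarray
    overall_percent_correct: float
    n_refits: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        df.index.name = "true"
        df.columns.name = "predicted"
        return df


def _priors_vector(priors, ns: np.ndarray) -> np.ndarray:
    if isinstance(priors, str):
        if priors == "equal":
            return np.full(len(ns), 1.0 / len(ns))
        if priors == "proportional":
            return ns / ns.sum()
        raise ParameterError(f"unknown priors {priors!r}")
    p = np.asarray(priors, dtype=np.float64)
    if p.shape != ns.shape or not np.isclose(p.sum(), 1.0):
        raise ParameterError("explicit priors must match group count and sum to 1")
    return p


def rao_f_approximation(
    wilks: float, p: int, k: int, N: int
) -> tuple[float, int, float, float]:
    """Rao's F approximation to the distribution of Wilks' lambda.

    Returns (F, df1, df2, p_value).  df1 = p(k-1); df2 = w*t - p(k-1)/2 + 1
    with w = N - 1 - (p+k)/2 and t = sqrt((p²(k-1)² - 4)/(p² + (k-1)² - 5))
    (t = 1 when the denominator degenerates).  df2 is returned unfloored;
    reporting floors it to an integer.
    """
    q = k - 1
    df1 = p * q
    denom = p**2 + q**2 - 5
    t = np.sqrt((p**2 * q**2 - 4.0) / denom) if denom > 0 and p * q > 2 else 1.0
    w = N - 1 - (p + k) / 2.0
    df2 = w * t - df1 / 2.0 + 1.0
    if df2 <= 0:
        return np.nan, df1, df2, np.nan
    if wilks <= 0:
        return np.inf, df1, df2, 0.0
    lam_t = wilks ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(sps.f.sf(F, df1, df2))
    return float(F), df1, float(df2), pval


def cda_fit(features, labels, priors="equal") -> CDAModel:
    """Fit a canonical discriminant analysis.

    Solves the generalized eigenproblem B v = λ W v (B between-group SSCP,
    W pooled within-group SSCP) and rescales eigenvectors so canonical
    scores have unit pooled within-group variance.  A singular W gets a
    small ridge (relative magnitude ``RIDGE_EPS``) with a warning.
    """
    X = np.asarray(
        features.to_numpy() if isinstance(features, pd.DataFrame) else features,
        dtype=np.float64,
    )
    y = np.asarray(labels)
    glabels = list(np.unique(y))
    k = len(glabels)
    N, p = X.shape
    if k < 2:
        raise InsufficientDataError("CDA needs at least 2 groups")
    if N < k:
        raise InsufficientDataError("CDA needs N >= k")

    ns = np.array([(y == g).sum() for g in glabels], dtype=np.float64)
    mus = np.vstack([X[y == g].mean(axis=0) for g in glabels])
    grand = X.mean(axis=0)

    B = (mus - grand).T @ ((mus - grand) * ns[:, None])
    W = np.zeros((p, p))
    for g, mu in zip(glabels, mus):
        R = X[y == g] - mu
        W += R.T @ R

    try:
        np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        ridge = RIDGE_EPS * np.trace(W) / p
        if ridge <= 0:
            ridge = RIDGE_EPS
        warnings.warn(
            "pooled within-group SSCP is singular; adding ridge "
            f"{ridge:.3e} to its diagonal",
            stacklevel=2,
        )
        W = W + ridge * np.eye(p)

    from scipy.linalg import eigh

    eigval, eigvec = eigh(B, W)           # ascending; vecs: v' W v = I
    order = np.argsort(eigval)[::-1]
    m = min(p, k - 1)
    lam = np.clip(eigval[order][:m], 0.0, None)
    # unit pooled within-group variance of canonical scores (degenerate
    # N == k case keeps a usable scale for distance-0 self-classification)
    V = eigvec[:, order][:, :m] * np.sqrt(max(N - k, 1))
    for j in range(V.shape[1]):           # deterministic sign
        lead = V[np.argmax(np.abs(V[:, j])), j]
        if lead < 0:
            V[:, j] *= -1.0

    wilks = float(np.prod(1.0 / (1.0 + lam)))
    F, df1, df2, pval = rao_f_approximation(wilks, p, k, N)

    return CDAModel(
        group_labels=glabels,
        priors=_priors_vector(priors, ns),
        canonical_coefficients=V,
        group_centroids=mus @ V,
        eigenvalues=lam,
        wilks_lambda=wilks,
        rao_F=F,
        df1=int(np.floor(df1)),
        df2=int(np.floor(df2)),
        p_value=pval,
        n_obs=N,
        n_features=p,
    )


def canonical_scores(model: CDAModel, features) -> np.ndarray:
    X = np.asarray(
        features.to_numpy() if isinstance(features, pd.DataFrame) else features,
        dtype=np.float64,
    )
    if X.shape[1] != model.n_features:
        raise ParameterError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    return X @ model.canonical_coefficients


def cda_classify(model: CDAModel, features, true_labels=None):
    """Classify observations with a fitted CDA model.

    Each observation goes to the group minimizing ½·d² - ln(prior), where d
    is the Euclidean distance to the group centroid in canonical space
    (equal to the pooled-covariance Mahalanobis distance).  If
    ``true_labels`` is given, a resubstitution confusion table is returned
    as well.
    """
    S = canonical_scores(model, features)
    d2 = ((S[:, None, :] - model.group_centroids[None, :, :]) ** 2).sum(axis=2)
    score = 0.5 * d2 - np.log(model.priors)[None, :]
    pred = np.array([model.group_labels[i] for i in np.argmin(score, axis=1)])
    if true_labels is None:
        return pred
    return pred, confusion_table(true_labels, pred, model.group_labels, "resubstitution")


def confusion_table(true_labels, predicted, labels, mode: str) -> ConfusionTable:
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    labels = list(labels)
    idx = {g: i for i, g in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, q in zip(true_labels, predicted):
        counts[idx[t], idx[q]] += 1
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row > 0, 100.0 * np.diag(counts) / row, np.nan)
    overall = 100.0 * np.trace(counts) / counts.sum()
    return ConfusionTable(
        mode=mode,
        labels=labels,
        counts=counts,
        percent_correct_per_group=pct,
        overall_percent_correct=float(overall),
    )


def jackknife_classify(features, labels, priors="equal") -> ConfusionTable:
    """Leave-one-out jackknife classification.

    Each observation is classified by a CDA refitted on the remaining
    N - 1 observations; the confusion table aggregates those N honest
    predictions.  A group of size one can never classify its own member
    correctly (its centroid vanishes from the training fold); a warning is
    emitted in that case.
    """
    X = np.asarray(
        features.to_numpy() if isinstance(features, pd.DataFrame) else features,
        dtype=np.float64,
    )
    y = np.asarray(labels)
    glabels = list(np.unique(y))
    ns = np.array([(y == g).sum() for g in glabels])
    if (ns == 1).any():
        singles = [g for g, n in zip(glabels, ns) if n == 1]
        warnings.warn(
            f"groups of size 1 ({singles}) can never be jackknife-classified "
            "correctly",
            stacklevel=2,
        )
    N = X.shape[0]
    if N < len(glabels) + 2:
        raise InsufficientDataError("jackknife needs N >= k + 2")
    preds = np.empty(N, dtype=object)
    n_refits = 0
    keep = np.ones(N, dtype=bool)
    for i in range(N):
        keep[i] = False
        model = cda_fit(X[keep], y[keep], priors=priors)
        n_refits += 1
        s = X[i : i + 1] @ model.canonical_coefficients
        d2 = ((s - model.group_centroids) ** 2).sum(axis=1)
        preds[i] = model.group_labels[
            int(np.argmin(0.5 * d2 - np.log(model.priors)))
        ]
        keep[i] = True
    table = confusion_table(y, preds, glabels, "jackknife")
    table.n_refits = n_refits
    return table


# --------------------------------------------------------------------------
# Face-combination pipeline step
# --------------------------------------------------------------------------

@dataclass
class FaceCombinationResult:
    model: CDAModel
    resubstitution: ConfusionTable
    jackknife: ConfusionTable
    pca_by_face: dict
    reduced_features: np.ndarray
    labels: np.ndarray
    level: str
    face_set: tuple


def run_face_combination_cda(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    face_set,
    level: str = "species",
    use_pca_reduction: bool = True,
    priors="equal",
) -> FaceCombinationResult:
    """Per-face PCA reduction followed by CDA with both classification modes.

    ``features``/``labels`` come from
    :func:`statomorph.efa.build_feature_matrix`.  When PCA reduction is on,
    each face's 76-column block is reduced separately with the Kaiser
    criterion and the retained scores are concatenated; the reduction is
    computed once on the full data set and held fixed during the jackknife
    (only the CDA is refitted per fold — PCA is a separate prior step of
    the procedure, not part of the classifier).
    """
    if level not in ("species", "family"):
        raise ParameterError(f"unknown grouping level {level!r}")
    face_set = tuple(f for f in ("proximal", "oral", "lateral") if f in set(face_set))
    if not face_set:
        raise ParameterError("face_set must not be empty")
    y = labels[level].to_numpy()

    pca_by_face: dict = {}
    if use_pca_reduction:
        blocks = []
        for face in face_set:
            suffix = {"proximal": "_prox", "oral": "_oral", "lateral": "_lat"}[face]
            cols = [c for c in features.columns if c.endswith(suffix)]
            sel = pca_select(features[cols], face=face)
            pca_by_face[face] = sel
            blocks.append(sel.scores)
        Xr = np.hstack(blocks)
    else:
        Xr = features.to_numpy(dtype=np.float64)

    model = cda_fit(Xr, y, priors=priors)
    _, resub = cda_classify(model, Xr, true_labels=y)
    jack = jackknife_classify(Xr, y, priors=priors)
    return FaceCombinationResult(
        model=model,
        resubstitution=resub,
        jackknife=jack,
        pca_by_face=pca_by_face,
        reduced_features=Xr,
        labels=y,
        level=level,
        face_set=face_set,
    )


def within_family_misclassification(
    table: ConfusionTable, species_to_family: dict
) -> tuple[float, float, int]:
    """Split misclassified counts into within-family and between-family.

    Returns (within_fraction, between_fraction, total_misclassified) for a
    species-level confusion table and a species -> family mapping.
    """
    within = between = 0
    for i, ti in enumerate(table.labels):
        for j, pj in enumerate(table.labels):
            if i == j:
                continue
            c = int(table.counts[i, j])
            if c == 0:
                continue
            if species_to_family[ti] == species_to_family[pj]:
                within += c
            else:
                between += c
    total = within + between
    if total == 0:
        return 0.0, 0.0, 0
    return within / total, between / total, total


# --------------------------------------------------------------------------
# Allometry
# --------------------------------------------------------------------------

def allometry_regression(mean_nef, length_um, species) -> pd.DataFrame:
    """Per-species OLS of mean NEF coefficient on statolith length.

    The response is each specimen's arithmetic mean over its feature-vector
    coefficients; the slope's t-test p-value answers whether shape drifts
    with size (allometry) within the species.  Requires n >= 3 per species
    and non-constant lengths.
    """
    mean_nef = np.asarray(mean_nef, dtype=np.float64)
    length_um = np.asarray(length_um, dtype=np.float64)
    species = np.asarray(species)
    rows = []
    for sp in np.unique(species):
        sel = species == sp
        n = int(sel.sum())
        if n < 3:
            raise InsufficientDataError(
                f"species {sp!r} has n={n}; allometry regression needs n >= 3"
            )
        if np.ptp(length_um[sel]) == 0:
            raise UndefinedSlopeError(
                f"species {sp!r} has constant statolith length"
            )
        res = sps.linregress(length_um[sel], mean_nef[sel])
        rows.append(
            (sp, n, res.slope, res.intercept, res.rvalue**2, res.pvalue)
        )
    return pd.DataFrame(
        rows, columns=["species", "n", "slope", "intercept", "r_squared", "p"]
    ).set_index("species")
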