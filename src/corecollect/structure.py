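"""Population structure: PCA, Tracy-Widom axis selection, K-means+BIC clustering,
discriminant-analysis memberships/covariates, Weir-Cockerham Fst and per-cluster
diversity summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import (
    GenotypeMatrix,
    ValidationError,
    allele_frequencies,
    rogers_distance,
)


@dataclass
class PCAResult:
    scores: np.ndarray  # n x K
    loadings: np.ndarray  # m x K, unit-norm columns
    eigenvalues: np.ndarray  # K, descending
    n_significant: int = 0


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray  # n ints in [0, k)
    memberships: np.ndarray  # n x k row-stochastic
    bic_curve: dict = field(default_factory=dict)
    Q: np.ndarray | None = None  # n x (k-1) covariates


@dataclass
class FstTable:
    labels: list
    fst: np.ndarray  # k x k, nan diagonal
    overall: float


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def standardize_genotypes(g: GenotypeMatrix) -> np.ndarray:
    """Center columns by 2p and scale by sqrt(2p(1-p)); p = alt-allele frequency."""
    if not g.is_complete:
        raise ValidationError("standardization requires complete genotypes")
    p = allele_frequencies(g).alt_freq
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("constant column: filter monomorphic markers first")
    return (g.dosage - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def pca(g: GenotypeMatrix, n_axes: int) -> PCAResult:
    """PCA of the standardized genotype matrix.

    ``eigenvalues`` are those of the sample covariance (divisor n-1), so they
    sum to the total standardized variance. Deterministic up to column sign.
    """
    if n_axes > min(g.n - 1, g.m):
        raise ValidationError("n_axes exceeds min(n-1, m)")
    X = standardize_genotypes(g)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes, :]
    # sign convention: largest-|.| loading positive
    for j in range(n_axes):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return PCAResult(scores=U * s, loadings=Vt.T,
                     eigenvalues=s**2 / (g.n - 1))


def subset_pca(g: GenotypeMatrix, subset, n_axes: int) -> PCAResult:
    """PCA of a row subset, standardized by subset frequencies.

    Markers monomorphic within the subset are zeroed out (zero variance, zero
    loading) so the loading dimension m matches the whole panel.
    """
    idx = np.asarray(subset, dtype=np.intp)
    x = g.dosage[idx, :]
    p = x.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    X = np.zeros_like(x)
    ok = sd > 0
    X[:, ok] = (x[:, ok] - 2.0 * p[ok]) / sd[ok]
    n_axes = min(n_axes, len(idx) - 1, g.m)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes, :]
    return PCAResult(scores=U * s, loadings=Vt.T,
                     eigenvalues=s**2 / max(len(idx) - 1, 1))


# ---------------------------------------------------------------------------
# Tracy-Widom axis selection
# ---------------------------------------------------------------------------

# TW(1) upper-tail quantiles (GOE Tracy-Widom distribution)
_TW1_TABLE = [
    (0.10, 0.4501),
    (0.05, 0.9793),
    (0.025, 1.4538),
    (0.01, 2.0234),
    (0.005, 2.4222),
    (0.001, 3.2724),
]


def tw_quantile(alpha: float) -> float:
    """TW(1) critical value at upper-tail probability alpha.

    Interpolates linearly in log10(alpha); clamps outside the table; alpha=0
    returns +inf (empty rejection region).
    """
    if alpha <= 0:
        return np.inf
    alphas = np.array([a for a, _ in _TW1_TABLE])
    qs = np.array([q for _, q in _TW1_TABLE])
    if alpha >= alphas[0]:
        return float(qs[0])
    if alpha <= alphas[-1]:
        return float(qs[-1])
    return float(np.interp(np.log10(alpha), np.log10(alphas[::-1]), qs[::-1]))


def tracy_widom_axes(p: PCAResult, n: int, m: int, alpha: float = 0.05) -> int:
    """Count of leading PCA axes significant under the Tracy-Widom test.

    Moment-matching normalization of successive eigenvalues: at each step the
    remaining eigenvalues define an effective marker count, the lead eigenvalue
    is normalized and compared to the TW(1) quantile; stops at the first
    non-significant axis.
    """
    if n < 3:
        raise ValidationError("need n >= 3 for Tracy-Widom testing")
    crit = tw_quantile(alpha)
    lam = np.asarray(p.eigenvalues, dtype=float)
    lam = lam[lam > 1e-12]
    count = 0
    for i in range(len(lam)):
        rest = lam[i:]
        k = len(rest)
        if k < 2:
            break
        s1, s2 = rest.sum(), (rest**2).sum()
        denom = (k - 1) * s2 - s1**2
        if denom <= 0:
            break
        n_eff = (k + 1) * s1**2 / denom
        if n_eff <= 1:
            break
        ell = k * rest[0] / s1
        mu = (np.sqrt(n_eff - 1) + np.sqrt(k)) ** 2 / n_eff
        sigma = ((np.sqrt(n_eff - 1) + np.sqrt(k)) / n_eff
                 * (1.0 / np.sqrt(n_eff - 1) + 1.0 / np.sqrt(k)) ** (1.0 / 3.0))
        tw = (ell - mu) / sigma
        if tw > crit:
            count += 1
        else:
            break
    return count


def pca_with_tw(g: GenotypeMatrix, n_axes: int | None = None,
                alpha: float = 0.05) -> PCAResult:
    """PCA plus Tracy-Widom significant-axis count filled in."""
    if n_axes is None:
        n_axes = min(g.n - 1, g.m, 50)
    res = pca(g, n_axes)
    res.n_significant = tracy_widom_axes(res, g.n, g.m, alpha)
    return res


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _kmeans_bic_value(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Spherical-Gaussian BIC of a K-means fit (X-means formulation).

    The mixing-proportion term sum n_i*log(n_i/n) is essential: without it a
    log-WSS criterion keeps rewarding splits of pure Gaussian clusters.
    """
    n, d = X.shape
    counts = np.bincount(labels, minlength=k).astype(float)
    centers = np.stack([X[labels == i].mean(axis=0) if counts[i] else
                        np.zeros(d) for i in range(k)])
    wss = float(((X - centers[labels]) ** 2).sum())
    sigma2 = max(wss / (d * max(n - k, 1)), 1e-300)
    nz = counts[counts > 0]
    ll = (float((nz * np.log(nz)).sum()) - n * np.log(n)
          - (n * d / 2.0) * np.log(2 * np.pi * sigma2)
          - d * (n - k) / 2.0)
    n_params = k * (d + 1)
    return -2.0 * ll + n_params * np.log(n)


def kmeans_bic(p: PCAResult, k_range=range(1, 11), seed: int = 0,
               n_restarts: int = 10, force_k: int | None = None) -> ClusterModel:
    """K-means over the Tracy-Widom-significant score columns, model picked by
    minimum spherical-Gaussian BIC; ``force_k`` overrides the argmin (expert
    designation)."""
    if p.n_significant < 1:
        raise ValidationError("no significant axes to cluster on")
    X = p.scores[:, :p.n_significant]
    n, d = X.shape
    ks = list(k_range)
    if max(ks) >= n:
        raise ValidationError("k_range upper bound must be < n")
    bic_curve: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in ks:
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed + k)
            labels = km.fit_predict(X)
        bic_curve[k] = _kmeans_bic_value(X, labels, k)
        fits[k] = labels
    best_k = force_k if force_k is not None else min(bic_curve, key=bic_curve.get)
    if best_k not in fits:
        if best_k >= n:
            raise ValidationError("forced k must be < n")
        km = KMeans(n_clusters=best_k, n_init=n_restarts, random_state=seed + best_k)
        fits[best_k] = km.fit_predict(X)
    labels = fits[best_k]
    member = np.zeros((n, best_k))
    member[np.arange(n), labels] = 1.0
    return ClusterModel(k=best_k, assignments=labels, memberships=member,
                        bic_curve=bic_curve)


def dapc_covariates(p: PCAResult, c: ClusterModel) -> ClusterModel:
    """Fit linear discriminant axes on the retained PCs with cluster labels;
    memberships become posterior class probabilities and Q the centered first
    (k-1) discriminant coordinates."""
    if c.k < 2:
        raise ValidationError("need k >= 2 clusters for discriminant analysis")
    counts = np.bincount(c.assignments, minlength=c.k)
    if (counts < 2).any():
        raise ValidationError("every cluster needs >= 2 members")
    # retain enough PC columns to support k-1 discriminant axes
    n_pc = min(max(p.n_significant, c.k - 1), p.scores.shape[1])
    X = p.scores[:, :max(n_pc, 1)]
    n_disc = min(c.k - 1, X.shape[1])
    lda = LinearDiscriminantAnalysis(n_components=n_disc)
    lda.fit(X, c.assignments)
    member = lda.predict_proba(X)
    member = member / member.sum(axis=1, keepdims=True)
    Q = lda.transform(X)[:, :n_disc]
    Q = Q - Q.mean(axis=0)
    return ClusterModel(k=c.k, assignments=c.assignments.copy(), memberships=member,
                        bic_curve=dict(c.bic_curve), Q=Q)


def cluster_model_from_labels(labels) -> ClusterModel:
    """Truth/externally-supplied labels as a ClusterModel (one-hot memberships,
    centered one-hot covariates)."""
    labels = np.asarray(labels, dtype=int)
    k = int(labels.max()) + 1
    n = len(labels)
    member = np.zeros((n, k))
    member[np.arange(n), labels] = 1.0
    Q = member[:, : k - 1] - member[:, : k - 1].mean(axis=0) if k > 1 else None
    return ClusterModel(k=k, assignments=labels, memberships=member, Q=Q)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------


def _wc_components(dosage: np.ndarray, labels: np.ndarray, pops) -> tuple[float, float]:
    """Sum over loci of the Weir-Cockerham a and a+b+c variance components."""
    r = len(pops)
    n_i = np.array([(labels == q).sum() for q in pops], dtype=float)
    if (n_i < 2).any():
        raise ValidationError("every population needs >= 2 members")
    p_i = np.stack([dosage[labels == q].mean(axis=0) / 2.0 for q in pops])  # r x m
    h_i = np.stack([(dosage[labels == q] == 1).mean(axis=0) for q in pops])
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return float(a.sum()), float((a + b + c).sum())


def wc_fst(dosage: np.ndarray, labels: np.ndarray, pops=None) -> float:
    """Multi-locus Weir-Cockerham theta (ratio of sums across loci)."""
    labels = np.asarray(labels)
    if pops is None:
        pops = sorted(set(labels.tolist()))
    if len(pops) < 2:
        raise ValidationError("need >= 2 populations")
    num, den = _wc_components(dosage, labels, pops)
    if den == 0:
        return 0.0
    return num / den


def pairwise_fst(g: GenotypeMatrix, c: ClusterModel) -> FstTable:
    """Pairwise and overall Weir-Cockerham Fst between clusters."""
    if c.k < 2:
        raise ValidationError("need >= 2 clusters")
    labels = c.assignments
    pops = list(range(c.k))
    fst = np.full((c.k, c.k), np.nan)
    for i in range(c.k):
        for j in range(i + 1, c.k):
            sel = np.isin(labels, [i, j])
            fst[i, j] = fst[j, i] = wc_fst(g.dosage[sel], labels[sel], [i, j])
    overall = wc_fst(g.dosage, labels, pops)
    return FstTable(labels=pops, fst=fst, overall=overall)


# ---------------------------------------------------------------------------
# per-cluster summaries
# ---------------------------------------------------------------------------


def cluster_summary(g: GenotypeMatrix, c: ClusterModel) -> pd.DataFrame:
    """Per-cluster n, ratio, SH, He, MRD, RAR plus a whole-collection row."""
    from . import evaluation as ev

    d = rogers_distance(g)
    rows = []
    whole = np.arange(g.n)
    for q in range(c.k):
        idx = np.flatnonzero(c.assignments == q)
        if idx.size == 0:
            raise ValidationError(f"cluster {q} is empty")
        rows.append(_summary_row(f"cluster_{q}", g, d, idx, whole))
    rows.append(_summary_row("whole", g, d, whole, whole))
    df = pd.DataFrame(rows)
    df["ratio"] = df["n"] / g.n
    df.loc[df.index[-1], "ratio"] = 1.0
    return df[["label", "n", "ratio", "SH", "He", "MRD", "RAR"]]


def _summary_row(label, g, d, idx, whole):
    from . import evaluation as ev

    from .genotypes import ValidationError as VErr

    try:
        rar = ev.eval_rar(g, idx)
    except VErr:  # panel without rare markers: metric undefined
        rar = np.nan
    return {
        "label": label,
        "n": int(len(idx)),
        "SH": ev.eval_sh(g, idx),
        "He": ev.eval_he(g, idx),
        "MRD": ev.eval_mrd(d, idx) if len(idx) >= 2 else 0.0,
        "RAR": rar,
    }
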