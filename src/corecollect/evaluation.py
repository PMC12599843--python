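"""Diversity and representativeness metrics for core collections, and the
composite index used to rank construction methods.

All subset arguments are integer row indices into the panel's accession axis.
Metrics that compare a core against the whole collection (CV, RAR, KL, COR, MD)
define the reference on the full panel passed in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    DistanceMatrix,
    GenotypeMatrix,
    ValidationError,
    allele_frequencies,
)
from .structure import PCAResult, pca_with_tw, subset_pca

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Per-collection metric bundle; ``I`` is filled by composite_index."""

    SH: float
    He: float
    MRD: float
    RAR: float
    CV: float
    KL: float
    COR: float
    MD: float | None = None
    QTL: float | None = None
    I: float | None = None
    method_label: str = ""
    replicate: int = 0


@dataclass
class TraitTable:
    accession_ids: list[str]
    traits: pd.DataFrame  # one column per trait, categorical (object) or numeric

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def is_categorical(self, name: str) -> bool:
        return not pd.api.types.is_numeric_dtype(self.traits[name])


def _check_subset(subset, n) -> np.ndarray:
    idx = np.asarray(subset, dtype=np.intp)
    if idx.size == 0:
        raise ValidationError("subset must be non-empty")
    if idx.min() < 0 or idx.max() >= n:
        raise ValidationError("subset index out of range")
    return idx


# ---------------------------------------------------------------------------
# diversity metrics
# ---------------------------------------------------------------------------


def eval_he(g: GenotypeMatrix, subset) -> float:
    """Expected heterozygosity: mean over loci of 1 - sum p_i^2."""
    idx = _check_subset(subset, g.n)
    p = g.dosage[idx, :].mean(axis=0) / 2.0
    return float(np.mean(1.0 - (p**2 + (1.0 - p) ** 2)))


def eval_sh(g: GenotypeMatrix, subset) -> float:
    """Shannon diversity: per-locus allele-frequency entropy (log2), averaged."""
    idx = _check_subset(subset, g.n)
    p = g.dosage[idx, :].mean(axis=0) / 2.0
    return float(np.mean(_entropy2(p) + _entropy2(1.0 - p)))


def _entropy2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = -p[nz] * np.log2(p[nz])
    return out


def eval_mrd(d: DistanceMatrix, subset) -> float:
    """Mean Rogers distance over unordered within-subset pairs."""
    idx = np.asarray(subset, dtype=np.intp)
    if idx.size < 2:
        raise ValidationError("MRD needs at least 2 accessions")
    sub = d.submatrix(idx)
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def eval_rar(g: GenotypeMatrix, subset, rare_maf: float = 0.10) -> float:
    """Fraction of whole-panel rare SNPs (MAF < rare_maf) still segregating in
    the subset (both alleles present)."""
    idx = _check_subset(subset, g.n)
    whole = allele_frequencies(g)
    rare = np.flatnonzero((whole.maf < rare_maf) & (whole.maf > 0))
    if rare.size == 0:
        raise ValidationError("no rare markers in whole collection; drop RAR")
    sub = allele_frequencies(g, idx)
    seg = sub.allele_presence[rare, 0] & sub.allele_presence[rare, 1]
    return float(seg.mean())


# ---------------------------------------------------------------------------
# representativeness metrics
# ---------------------------------------------------------------------------


def eval_cv(g: GenotypeMatrix, subset) -> float:
    """Allelic coverage: mean per-locus (alleles in subset)/(alleles in panel)."""
    idx = _check_subset(subset, g.n)
    whole = allele_frequencies(g).allele_presence.sum(axis=1).astype(float)
    sub_p = allele_frequencies(g, idx).allele_presence
    sub = sub_p.sum(axis=1).astype(float)
    whole = np.maximum(whole, 1.0)
    return float(np.mean(np.minimum(sub, whole) / whole))


def eval_kl(g: GenotypeMatrix, subset, epsilon: float | None = None) -> float:
    """Kullback-Leibler-style divergence of core vs whole minor-allele
    frequencies: sum_j p_j ln(p_j/q_j), minor allele anchored in the whole
    collection, zero frequencies floored at epsilon (default 1/(2s+1))."""
    idx = _check_subset(subset, g.n)
    if epsilon is None:
        epsilon = 1.0 / (2.0 * len(idx) + 1.0)
    whole = allele_frequencies(g)
    # identify the whole-collection minor allele per marker and track it
    minor_is_alt = whole.alt_freq <= 0.5
    q = np.where(minor_is_alt, whole.alt_freq, 1.0 - whole.alt_freq)
    sub_alt = g.dosage[idx, :].mean(axis=0) / 2.0
    p = np.where(minor_is_alt, sub_alt, 1.0 - sub_alt)
    p = np.maximum(p, epsilon)
    q = np.maximum(q, epsilon)
    return float(np.sum(p * np.log(p / q)))


def eval_cor(g: GenotypeMatrix, subset, whole_pca: PCAResult | None = None,
             alpha: float = 0.05) -> float:
    """Eigenvalue-weighted mean absolute correlation of same-rank marker-loading
    vectors between subset PCA and whole-panel PCA, via Fisher's z."""
    idx = _check_subset(subset, g.n)
    if whole_pca is None:
        whole_pca = pca_with_tw(g, alpha=alpha)
    n_axes = max(whole_pca.n_significant, 1)
    if len(idx) < n_axes + 1:
        raise ValidationError("subset smaller than significant-axis count + 1")
    sub = subset_pca(g, idx, n_axes)
    k = min(n_axes, sub.loadings.shape[1])
    r = np.empty(k)
    for i in range(k):
        a, b = whole_pca.loadings[:, i], sub.loadings[:, i]
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        r[i] = 0.0 if denom == 0 else abs(float(a @ b) / denom)
    z = np.arctanh(np.clip(r, 0.0, 1.0 - 1e-12))
    w = whole_pca.eigenvalues[:k]
    zbar = float(np.average(z, weights=w))
    return float(np.tanh(zbar))


def cramers_v(x: pd.Series, y: pd.Series) -> float:
    """Cramer's V association between two categorical variables."""
    tab = pd.crosstab(x, y)
    if tab.size == 0 or min(tab.shape) < 2:
        return 0.0
    chi2 = stats.chi2_contingency(tab.values, correction=False)[0]
    n = tab.values.sum()
    return float(np.sqrt(chi2 / (n * (min(tab.shape) - 1))))


def eval_md(t: TraitTable, subset, alpha: float = 0.05,
            v_max: float = 0.7) -> float:
    """Fraction of (Cramer's-V-deduplicated) traits differing significantly
    between subset and whole collection.

    Categorical traits: chi-square goodness-of-fit of subset counts against
    whole-collection proportions. Quantitative traits: two-sample KS test.
    """
    idx = _check_subset(subset, len(t.accession_ids))
    names = list(t.trait_names)
    cats = [n for n in names if t.is_categorical(n)]
    dropped: set[str] = set()
    for i, a in enumerate(cats):
        if a in dropped:
            continue
        for b in cats[i + 1:]:
            if b in dropped:
                continue
            if cramers_v(t.traits[a], t.traits[b]) > v_max:
                dropped.add(b)  # greedily drop the later trait
    surviving = [n for n in names if n not in dropped]
    if not surviving:
        raise ValidationError("all traits dropped by Cramer's V preselection")
    sig = 0
    for name in surviving:
        col = t.traits[name]
        if t.is_categorical(name):
            levels = col.value_counts()
            levels = levels[levels > 0]
            obs = col.iloc[idx].value_counts().reindex(levels.index, fill_value=0)
            expected = levels / levels.sum() * len(idx)
            pval = stats.chisquare(obs.values, expected.values).pvalue
        else:
            pval = stats.ks_2samp(col.iloc[idx].values, col.values).pvalue
        if pval < alpha:
            sig += 1
    return sig / len(surviving)


# ---------------------------------------------------------------------------
# composite index
# ---------------------------------------------------------------------------

_INDEX_SIGNS = {"SH": 1, "He": 1, "RAR": 1, "CV": 1, "COR": 1, "KL": -1, "QTL": 1}


def composite_index(reports: list[EvaluationReport],
                    require_qtl: bool = True) -> list[EvaluationReport]:
    """Fill the composite index I = mean of signed z-scores of the seven
    components (SH, He, RAR, CV, COR, -KL, QTL), standardized across the
    supplied reports with the sample standard deviation. Zero-variance
    components contribute 0. MD is deliberately excluded."""
    if len(reports) < 2:
        raise ValidationError("composite index needs >= 2 reports")
    comps = dict(_INDEX_SIGNS)
    if any(r.QTL is None for r in reports):
        if require_qtl:
            raise ValidationError("QTL component missing from some reports")
        comps.pop("QTL")
    z = {}
    for name in comps:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        sd = vals.std(ddof=1)
        # zero-variance must be judged relatively: std of identical floats can
        # come out as ~1e-16 and would blow up into O(1) z-scores
        if sd <= 1e-12 * max(1.0, np.abs(vals).max()):
            z[name] = np.zeros_like(vals)
        else:
            z[name] = (vals - vals.mean()) / sd
    k = len(comps)
    for i, r in enumerate(reports):
        r.I = float(sum(sign * z[name][i] for name, sign in comps.items()) / k)
    return reports


# ---------------------------------------------------------------------------
# whole-collection evaluation driver
# ---------------------------------------------------------------------------


def evaluate_core(g: GenotypeMatrix, subset, d: DistanceMatrix,
                  whole_pca: PCAResult | None = None,
                  traits: TraitTable | None = None,
                  method_label: str = "", replicate: int = 0,
                  rare_maf: float = 0.10) -> EvaluationReport:
    """Compute the full metric bundle (QTL left to qtl_bench)."""
    idx = _check_subset(subset, g.n)
    return EvaluationReport(
        SH=eval_sh(g, idx),
        He=eval_he(g, idx),
        MRD=eval_mrd(d, idx),
        RAR=eval_rar(g, idx, rare_maf=rare_maf),
        CV=eval_cv(g, idx),
        KL=eval_kl(g, idx),
        COR=eval_cor(g, idx, whole_pca=whole_pca),
        MD=None if traits is None else eval_md(traits, idx),
        method_label=method_label,
        replicate=replicate,
    )


def report_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Mean and sample-sd per metric per method label (Table-3-style layout)."""
    rows = [
        {
            "method": r.method_label,
            "replicate": r.replicate,
            **{k: getattr(r, k) for k in
               ("SH", "He", "MRD", "RAR", "CV", "KL", "COR", "MD", "QTL", "I")},
        }
        for r in reports
    ]
    df = pd.DataFrame(rows)
    df = df.drop(columns=[c for c in df.columns if df[c].isna().all()])
    for c in df.columns:
        if c not in ("method",):
            df[c] = pd.to_numeric(df[c])
    agg = df.groupby("method").agg(["mean", lambda s: s.std(ddof=1)])
    agg.columns = [f"{m}_{'sd' if fn == '<lambda_0>' else fn}" for m, fn in agg.columns]
    return agg.reset_index()
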