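"""QTL-recovery benchmarking: trait simulation with known causal SNPs,
mixed-linear-model GWAS (variance components estimated once under the null,
per-SNP Wald tests in the whitened model), genomic-control lambda, the
effective-test-count significance threshold, and the common-QTL ratio."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as sopt
from scipy import stats

from .genotypes import GenotypeMatrix, KinshipMatrix, ValidationError, kinship_vanraden

logger = logging.getLogger(__name__)

_CHI2_MEDIAN_1DF = 0.4549364231195724  # median of chi-square with 1 df


@dataclass
class TraitSimulation:
    trait_values: np.ndarray  # n x T
    causal_index: list[np.ndarray]  # per trait
    effects: list[np.ndarray]  # per trait
    h2_qtl: float
    h2_poly: float
    seed: int
    trait_names: list[str] = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return self.trait_values.shape[1]

    @property
    def n_causal_total(self) -> int:
        return int(sum(len(c) for c in self.causal_index))


@dataclass
class GWASResult:
    pvalues: np.ndarray
    sigma_g2: float
    sigma_e2: float
    lambda_gc: float
    threshold: float
    significant: set
    betas: np.ndarray | None = None


@dataclass
class BenchmarkReport:
    rows: pd.DataFrame  # per (method, replicate): qtl_ratio, mean lambda
    whole_lambdas: np.ndarray  # per-trait lambda on the whole panel
    n_causal: int
    n_whole_detected: int

    def aggregate(self) -> pd.DataFrame:
        return (self.rows.groupby("method")["qtl_ratio"]
                .agg(["mean", lambda s: s.std(ddof=1)])
                .rename(columns={"<lambda_0>": "sd"}).reset_index())


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------


def _scale_to_var(x: np.ndarray, target: float, rng=None) -> np.ndarray:
    v = x.var()
    if target <= 0:
        return np.zeros_like(x)
    if v <= 0:
        return x
    return x * np.sqrt(target / v)


def simulate_traits(g: GenotypeMatrix, per_chrom_traits: int = 2,
                    qtl_per_trait: int = 31, h2_qtl: float = 0.4,
                    h2_poly: float = 0.2, seed: int = 0,
                    chromosomes=None, K: KinshipMatrix | None = None) -> TraitSimulation:
    """Simulate ``per_chrom_traits`` traits per chromosome, each with
    ``qtl_per_trait`` causal SNPs drawn from that chromosome.

    Trait = QTL score (variance h2_qtl) + kinship-distributed polygenic term
    (variance h2_poly) + white noise (variance 1-h2_qtl-h2_poly), standardized
    to unit sample variance.
    """
    if h2_qtl + h2_poly > 1:
        raise ValidationError("h2_qtl + h2_poly must be <= 1")
    rng = np.random.default_rng(seed)
    if chromosomes is None:
        chromosomes = g.chromosomes()
    if K is None and h2_poly > 0:
        K = kinship_vanraden(g)
    chrom_str = g.chrom.astype(str)
    L = None
    if h2_poly > 0:
        w, V = np.linalg.eigh(K.K)
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)
    traits, causal, effects, names = [], [], [], []
    for c in chromosomes:
        cidx = np.flatnonzero(chrom_str == str(c))
        if cidx.size < qtl_per_trait:
            raise ValidationError(
                f"chromosome {c} has {cidx.size} markers < qtl_per_trait")
        for t in range(per_chrom_traits):
            ci = np.sort(rng.choice(cidx, size=qtl_per_trait, replace=False))
            b = rng.standard_normal(qtl_per_trait)
            raw = g.dosage[:, ci] @ b
            if raw.var() > 0 and h2_qtl > 0:
                b = b * np.sqrt(h2_qtl / raw.var())
            score = g.dosage[:, ci] @ b
            y = score.copy()
            if h2_poly > 0:
                poly = _scale_to_var(L @ rng.standard_normal(g.n), h2_poly)
                y = y + poly
            noise_var = 1.0 - h2_qtl - h2_poly
            if noise_var > 0:
                y = y + _scale_to_var(rng.standard_normal(g.n), noise_var)
            sd = y.std()
            if sd > 0:
                y = (y - y.mean()) / sd
                b = b / sd  # keep stored effects on the trait's final scale
            traits.append(y)
            causal.append(ci)
            effects.append(b)
            names.append(f"chr{c}_t{t + 1}")
    return TraitSimulation(trait_values=np.column_stack(traits),
                           causal_index=causal, effects=effects,
                           h2_qtl=h2_qtl, h2_poly=h2_poly, seed=seed,
                           trait_names=names)


# ---------------------------------------------------------------------------
# mixed-model GWAS (EMMAX / P3D)
# ---------------------------------------------------------------------------


def _reml_delta(yr: np.ndarray, Xr: np.ndarray, w: np.ndarray) -> float:
    """REML estimate of delta = sigma_e^2/sigma_g^2 in rotated coordinates
    (w are kinship eigenvalues). Golden-section on log10(delta)."""
    n, p = Xr.shape

    def neg_reml_ll(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        d = w + delta
        Xi = Xr / d[:, None]
        XtVX = Xr.T @ Xi
        try:
            beta = np.linalg.solve(XtVX, Xi.T @ yr)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        rss = float(r @ (r / d))
        if rss <= 0:
            return np.inf
        sg2 = rss / (n - p)
        _, ld_XtVX = np.linalg.slogdet(XtVX)
        _, ld_XtX = np.linalg.slogdet(Xr.T @ Xr)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sg2) + np.log(d).sum()
                     + ld_XtVX - ld_XtX + (n - p))
        return -ll

    res = sopt.minimize_scalar(neg_reml_ll, bounds=(-6.0, 6.0), method="bounded",
                               options={"xatol": 1e-6})
    return 10.0 ** float(res.x)


def mlm_gwas(g: GenotypeMatrix, y: np.ndarray, Q: np.ndarray | None,
             K: KinshipMatrix, threshold: float = 0.05,
             eig: tuple[np.ndarray, np.ndarray] | None = None,
             rotated_G: np.ndarray | None = None) -> GWASResult:
    """Mixed-model association scan y = mu*1 + Q c + b x + g + e.

    The null model variance components are estimated by REML via the
    eigendecomposition of K; each SNP is then tested by a Wald t-test with the
    components held fixed (P3D). ``eig``/``rotated_G`` allow reuse across
    traits on the same panel.
    """
    y = np.asarray(y, dtype=float)
    n = g.n
    if y.shape[0] != n:
        raise ValidationError("trait length mismatch")
    X = np.ones((n, 1)) if Q is None or Q.size == 0 else np.column_stack(
        [np.ones(n), Q])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("collinear covariate columns")
    if eig is None:
        w, V = np.linalg.eigh(K.K)
        if w.min() < -1e-8:
            logger.warning("kinship not PSD (min eig %.2e); clipping", w.min())
        w = np.clip(w, 0.0, None)
        eig = (w, V)
    w, V = eig
    yr = V.T @ y
    Xr = V.T @ X
    delta = _reml_delta(yr, Xr, w)
    d = w + delta
    Xi = Xr / d[:, None]
    beta = np.linalg.solve(Xr.T @ Xi, Xi.T @ yr)
    r = yr - Xr @ beta
    sg2 = float(r @ (r / d)) / (n - X.shape[1])
    se2 = delta * sg2

    # whiten and residualize against covariates
    s = 1.0 / np.sqrt(d)
    yw = yr * s
    Xw = Xr * s[:, None]
    Gw = (V.T @ g.dosage) * s[:, None] if rotated_G is None else rotated_G * s[:, None]
    Qx, _ = np.linalg.qr(Xw)
    yt = yw - Qx @ (Qx.T @ yw)
    Gt = Gw - Qx @ (Qx.T @ Gw)
    xx = np.einsum("ij,ij->j", Gt, Gt)
    xy = Gt.T @ yt
    ok = xx > 1e-12
    b = np.zeros(g.m)
    tstat = np.zeros(g.m)
    b[ok] = xy[ok] / xx[ok]
    dof = n - X.shape[1] - 1
    rss = float(yt @ yt) - b**2 * xx
    rss = np.maximum(rss, 1e-300)
    sigma2 = rss / dof
    tstat[ok] = b[ok] / np.sqrt(sigma2[ok] / xx[ok])
    pvals = np.ones(g.m)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    lam = genomic_lambda_from_pvalues(pvals)
    sig = {g.marker_ids[j] for j in np.flatnonzero(pvals < threshold)}
    return GWASResult(pvalues=pvals, sigma_g2=sg2, sigma_e2=se2,
                      lambda_gc=lam, threshold=threshold, significant=sig,
                      betas=b)


def genomic_lambda_from_pvalues(pvals: np.ndarray) -> float:
    """lambda = median(chi2_1 quantile of 1-p) / chi2_1 median."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size < 100:
        logger.warning("genomic lambda computed on only %d tests", pvals.size)
    chi = stats.chi2.isf(np.clip(pvals, np.finfo(float).tiny, 1.0), df=1)
    return float(np.median(chi) / _CHI2_MEDIAN_1DF)


def genomic_lambda(r: GWASResult) -> float:
    return genomic_lambda_from_pvalues(r.pvalues)


def gao_threshold(g: GenotypeMatrix, c_explained: float = 0.995,
                  alpha: float = 0.05) -> float:
    """Effective-test-count threshold: per chromosome, the smallest number of
    leading correlation-matrix eigenvalues whose sum reaches ``c_explained`` of
    the trace; Meff summed over chromosomes; returns alpha / Meff."""
    if g.m < 2:
        raise ValidationError("need >= 2 markers")
    if not g.is_complete:
        raise ValidationError("gao_threshold requires complete genotypes")
    chrom_str = g.chrom.astype(str)
    meff = 0
    for c in g.chromosomes():
        cidx = np.flatnonzero(chrom_str == str(c))
        x = g.dosage[:, cidx]
        sd = x.std(axis=0)
        keep = sd > 0
        if keep.sum() == 0:
            continue
        if keep.sum() == 1:
            meff += 1
            continue
        R = np.corrcoef(x[:, keep], rowvar=False)
        ev = np.linalg.eigvalsh(R)[::-1]
        ev = np.clip(ev, 0.0, None)
        cum = np.cumsum(ev)
        target = c_explained * ev.sum()
        meff += int(np.searchsorted(cum, target - 1e-12) + 1)
    if meff == 0:
        raise ValidationError("no polymorphic markers")
    return alpha / meff


def qtl_overlap(whole: dict, core: dict, marker_pos: dict | None = None,
                window_bp: int = 0) -> float:
    """(common core QTLs)/(total whole-collection QTLs), pooled over traits.

    ``whole``/``core`` map trait name -> set of significant marker ids. With
    window_bp > 0, ``marker_pos`` maps marker id -> (chrom, pos) and a core hit
    matches any whole hit for the same trait within window_bp on the same
    chromosome.
    """
    total_whole = sum(len(s) for s in whole.values())
    if total_whole == 0:
        raise ValidationError("empty whole-collection QTL set")
    common = 0
    for trait, wset in whole.items():
        cset = core.get(trait, set())
        if window_bp == 0:
            common += len(cset & wset)
        else:
            if marker_pos is None:
                raise ValidationError("window matching needs marker positions")
            wpos = [marker_pos[m] for m in wset]
            for m in cset:
                ch, p = marker_pos[m]
                if any(ch == wc and abs(p - wp) <= window_bp for wc, wp in wpos):
                    common += 1
    return common / total_whole


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------


def _gwas_all_traits(g, traits: TraitSimulation, Q, K, threshold):
    w, V = np.linalg.eigh(K.K)
    w = np.clip(w, 0.0, None)
    rotG = V.T @ g.dosage
    results = {}
    lambdas = []
    for t in range(traits.n_traits):
        name = traits.trait_names[t] if traits.trait_names else f"trait_{t}"
        res = mlm_gwas(g, traits.trait_values[:, t], Q, K, threshold=threshold,
                       eig=(w, V), rotated_G=rotG)
        results[name] = res
        lambdas.append(res.lambda_gc)
    return results, np.array(lambdas)


def run_benchmark(g: GenotypeMatrix, traits: TraitSimulation, selections,
                  cluster_Q: np.ndarray | None, K: KinshipMatrix,
                  threshold: float | None = None) -> BenchmarkReport:
    """Whole-panel GWAS once per trait, then GWAS on each core (rows of y, Q, K
    and genotypes subset; covariates are NOT re-estimated on the core), common-
    QTL ratio per core, mean/sd per method label."""
    if threshold is None:
        threshold = gao_threshold(g)
    whole_res, whole_lams = _gwas_all_traits(g, traits, cluster_Q, K, threshold)
    whole_sig = {t: r.significant for t, r in whole_res.items()}
    n_whole = sum(len(s) for s in whole_sig.values())
    if n_whole == 0:
        raise ValidationError("no QTL detected on the whole panel; "
                              "increase heritability or panel size")
    rows = []
    for sel in selections:
        idx = g.index_of(sel.selected_ids)
        min_n = (0 if cluster_Q is None else cluster_Q.shape[1]) + 2
        if len(idx) < min_n:
            raise ValidationError("core smaller than covariate count + 2")
        g_sub = g.take_accessions(idx)
        K_sub = KinshipMatrix([g.accession_ids[i] for i in idx], K.submatrix(idx))
        Q_sub = None if cluster_Q is None else cluster_Q[idx, :]
        if Q_sub is not None:
            # drop covariate columns that lose rank in the subset
            keep = []
            for j in range(Q_sub.shape[1]):
                trial = Q_sub[:, keep + [j]]
                if np.linalg.matrix_rank(np.column_stack([np.ones(len(idx)), trial])) \
                        == len(keep) + 2:
                    keep.append(j)
            Q_sub = Q_sub[:, keep] if keep else None
        sub_traits = TraitSimulation(
            trait_values=traits.trait_values[idx, :],
            causal_index=traits.causal_index, effects=traits.effects,
            h2_qtl=traits.h2_qtl, h2_poly=traits.h2_poly, seed=traits.seed,
            trait_names=traits.trait_names)
        core_res, core_lams = _gwas_all_traits(g_sub, sub_traits, Q_sub, K_sub,
                                               threshold)
        core_sig = {t: r.significant for t, r in core_res.items()}
        ratio = qtl_overlap(whole_sig, core_sig)
        rows.append({"method": sel.method_label, "replicate": sel.replicate,
                     "size": len(idx), "qtl_ratio": ratio,
                     "mean_lambda": float(core_lams.mean())})
    return BenchmarkReport(rows=pd.DataFrame(rows), whole_lambdas=whole_lams,
                           n_causal=traits.n_causal_total,
                           n_whole_detected=n_whole)
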