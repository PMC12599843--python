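"""Seeded generation of structured genotype panels (Balding-Nichols demes with
optional autoregressive within-chromosome LD and partial selfing) and
cluster-associated passport traits, so the whole toolkit is testable without
any external data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import TraitTable
from .genotypes import GenotypeMatrix, ValidationError
from .structure import ClusterModel, cluster_model_from_labels


@dataclass
class PanelSpec:
    n_per_cluster: list[int]
    fst: float
    m: int
    n_chrom: int = 15
    maf_range: tuple[float, float] = (0.1, 0.9)
    selfing: float = 0.98
    ld_rho: float = 0.6  # AR(1) latent correlation between adjacent markers
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.n_per_cluster) < 20:
            raise ValidationError("panel must have >= 20 accessions")
        if not (0.0 < self.fst < 1.0):
            raise ValidationError("fst must be in (0,1)")
        if self.m < self.n_chrom:
            raise ValidationError("need m >= n_chrom")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("maf_range must satisfy 0 < min < max < 1")

    @property
    def n_clusters(self) -> int:
        return len(self.n_per_cluster)

    @property
    def n(self) -> int:
        return sum(self.n_per_cluster)


@dataclass
class PanelBundle:
    genotypes: GenotypeMatrix
    truth: ClusterModel
    traits: TraitTable | None = None
    spec: PanelSpec | None = None


def _chromosome_map(m: int, n_chrom: int, rng: np.random.Generator):
    sizes = np.full(n_chrom, m // n_chrom)
    sizes[: m % n_chrom] += 1
    chroms, poss = [], []
    for c, size in enumerate(sizes, start=1):
        p = np.sort(rng.choice(np.arange(1, 25_000_000), size=size, replace=False))
        chroms.extend([str(c)] * size)
        poss.extend(p.tolist())
    return np.array(chroms, dtype=object), np.array(poss, dtype=np.int64)


def _ar1_latent(rng, n, chrom, rho):
    """n x m latent Gaussians with AR(1) correlation rho between adjacent
    markers within each chromosome."""
    m = len(chrom)
    z = rng.standard_normal((n, m))
    if rho <= 0:
        return z
    out = np.empty_like(z)
    start = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        out[:, idx[0]] = z[:, idx[0]]
        for j0, j1 in zip(idx[:-1], idx[1:]):
            out[:, j1] = rho * out[:, j0] + np.sqrt(1 - rho**2) * z[:, j1]
    return out


def generate_panel(spec: PanelSpec) -> tuple[GenotypeMatrix, ClusterModel]:
    """Balding-Nichols panel: deme frequencies Beta(p0(1-F)/F, (1-p0)(1-F)/F)
    around Uniform(maf_range) ancestral frequencies; genotypes drawn with
    inbreeding coefficient ``selfing`` via a shared-allele copula; optional
    AR(1) LD between adjacent markers. Returns the panel and truth labels."""
    rng = np.random.default_rng(spec.seed)
    F = spec.fst
    a_scale = (1.0 - F) / F
    lo, hi = spec.maf_range
    p0 = rng.uniform(lo, hi, size=spec.m)
    cluster_freq = np.empty((spec.n_clusters, spec.m))
    for c in range(spec.n_clusters):
        p = rng.beta(p0 * a_scale, (1.0 - p0) * a_scale)
        # resample degenerate draws (Beta mass at 0/1 gives monomorphic demes;
        # tolerated, but exact 0/1 breaks nothing downstream)
        cluster_freq[c] = np.clip(p, 0.0, 1.0)
    chrom, pos = _chromosome_map(spec.m, spec.n_chrom, rng)
    labels = np.repeat(np.arange(spec.n_clusters), spec.n_per_cluster)
    dosage = np.empty((spec.n, spec.m))
    row = 0
    for c, nc in enumerate(spec.n_per_cluster):
        pfreq = cluster_freq[c]
        z1 = _ar1_latent(rng, nc, chrom, spec.ld_rho)
        z2 = _ar1_latent(rng, nc, chrom, spec.ld_rho)
        thresh = stats.norm.ppf(np.clip(pfreq, 1e-12, 1 - 1e-12))
        a1 = (z1 < thresh).astype(float)
        a2_indep = (z2 < thresh).astype(float)
        share = rng.random((nc, spec.m)) < spec.selfing
        a2 = np.where(share, a1, a2_indep)
        dosage[row:row + nc] = a1 + a2
        row += nc
    ids = [f"acc{str(i).zfill(4)}" for i in range(spec.n)]
    mids = [f"snp{str(j).zfill(5)}" for j in range(spec.m)]
    g = GenotypeMatrix(ids, mids, chrom, pos, dosage)
    return g, cluster_model_from_labels(labels)


def generate_traits(truth: ClusterModel, n_cat: int, n_quant: int,
                    cluster_effect: float, seed: int = 0,
                    accession_ids=None) -> TraitTable:
    """Passport-style traits with cluster-dependent distributions.

    Categorical traits: per-cluster Dirichlet category probabilities whose
    concentration decreases with ``cluster_effect`` (0 -> identical across
    clusters). Quantitative traits: cluster mean shifts of size
    ``cluster_effect`` plus unit noise.
    """
    if n_cat < 0 or n_quant < 0:
        raise ValidationError("trait counts must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(truth.assignments)
    k = truth.k
    if accession_ids is None:
        accession_ids = [f"acc{str(i).zfill(4)}" for i in range(n)]
    cols = {}
    for t in range(n_cat):
        n_levels = int(rng.integers(2, 5))
        base = rng.dirichlet(np.ones(n_levels) * 5.0)
        vals = np.empty(n, dtype=object)
        for c in range(k):
            if cluster_effect <= 0:
                probs = base
            else:
                conc = base * max(5.0 / cluster_effect, 1e-3)
                probs = rng.dirichlet(conc)
            members = np.flatnonzero(truth.assignments == c)
            draws = rng.choice(n_levels, size=members.size, p=probs)
            vals[members] = np.array([f"L{v}" for v in draws], dtype=object)
        cols[f"cat{t + 1}"] = vals
    for t in range(n_quant):
        shifts = rng.standard_normal(k) * cluster_effect
        cols[f"quant{t + 1}"] = shifts[truth.assignments] + rng.standard_normal(n)
    df = pd.DataFrame(cols, index=range(n))
    return TraitTable(accession_ids=list(accession_ids), traits=df)


STANDARD_SIZES = (140, 190, 45, 45, 120, 60)  # ~ (23, 31, 7, 8, 20, 11)% of 600


def standard_fixture(seed: int = 0, m: int = 3000, n_chrom: int = 15,
                     with_traits: bool = True) -> PanelBundle:
    """The canonical desk-scale panel: 6 clusters of sizes (140,190,45,45,120,60),
    3,000 SNPs on 15 chromosomes, divergence 0.19, selfing 0.98, plus 10
    categorical and 2 quantitative passport traits."""
    spec = PanelSpec(n_per_cluster=list(STANDARD_SIZES), fst=0.19, m=m,
                     n_chrom=n_chrom, maf_range=(0.1, 0.9), selfing=0.98,
                     seed=seed)
    g, truth = generate_panel(spec)
    traits = None
    if with_traits:
        traits = generate_traits(truth, n_cat=10, n_quant=2, cluster_effect=1.5,
                                 seed=seed + 1, accession_ids=g.accession_ids)
    return PanelBundle(genotypes=g, truth=truth, traits=traits, spec=spec)


def write_fixture(bundle: PanelBundle, outdir) -> None:
    """Dump a bundle as plain-text assets (matrix TSV, trait TSV, truth TSV)."""
    from pathlib import Path

    from .genotypes import write_matrix_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(bundle.genotypes, outdir / "genotypes.tsv")
    pd.DataFrame({"accession": bundle.genotypes.accession_ids,
                  "cluster": bundle.truth.assignments}).to_csv(
        outdir / "truth_labels.tsv", sep="\t", index=False)
    if bundle.traits is not None:
        df = bundle.traits.traits.copy()
        df.insert(0, "accession", bundle.traits.accession_ids)
        df.to_csv(outdir / "traits.tsv", sep="\t", index=False)
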