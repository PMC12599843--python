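"""Genotype data model, file I/O, quality filters, LD pruning and relationship matrices.

Dosage convention: copies of the alternate allele, 0/1/2, NaN for missing.
Markers are kept sorted by (chromosome, position); positions are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

MISSING = np.nan


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """n accessions x m biallelic SNPs, dosage coded, with a chromosome map."""

    accession_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray  # per-marker chromosome label (str)
    pos: np.ndarray  # per-marker 1-based position (int)
    dosage: np.ndarray  # n x m float array, values in {0,1,2,NaN}

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        n, m = self.dosage.shape
        if n < 2:
            raise ValidationError(f"need at least 2 accessions, got {n}")
        if m < 1:
            raise ValidationError("need at least 1 marker")
        if len(self.accession_ids) != n or len(self.marker_ids) != m:
            raise ValidationError("id lists inconsistent with dosage shape")
        if len(set(self.accession_ids)) != n:
            raise ValidationError("duplicate accession ids")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker ids")
        if np.any(self.pos <= 0):
            raise ValidationError("positions must be positive")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosage values must be in {0,1,2,missing}")

    # -- basic accessors -----------------------------------------------------

    @property
    def n(self) -> int:
        return self.dosage.shape[0]

    @property
    def m(self) -> int:
        return self.dosage.shape[1]

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.dosage).any()

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def take_accessions(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            [self.accession_ids[i] for i in idx],
            list(self.marker_ids),
            self.chrom.copy(),
            self.pos.copy(),
            self.dosage[idx, :].copy(),
        )

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        if idx.size == 0:
            raise ValidationError("all markers removed")
        return GenotypeMatrix(
            list(self.accession_ids),
            [self.marker_ids[i] for i in idx],
            self.chrom[idx].copy(),
            self.pos[idx].copy(),
            self.dosage[:, idx].copy(),
        )

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in lookup]
        if missing:
            raise ValidationError(f"accession ids not in panel: {missing[:10]}")
        return np.array([lookup[a] for a in ids], dtype=np.intp)

    def sorted_by_map(self) -> "GenotypeMatrix":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.take_markers(order)


@dataclass
class AlleleFrequencySet:
    """Per-marker allele frequencies and presence flags for a set of calls."""

    maf: np.ndarray
    alt_freq: np.ndarray
    allele_presence: np.ndarray  # m x 2 bool: (ref observed, alt observed)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # n x n symmetric, zero diagonal

    def submatrix(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.intp)
        return self.d[np.ix_(idx, idx)]


@dataclass
class KinshipMatrix:
    ids: list[str]
    K: np.ndarray

    def submatrix(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.intp)
        return self.K[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(g: GenotypeMatrix, subset=None) -> AlleleFrequencySet:
    """Alternate-allele frequency, MAF and allele presence per marker.

    Computed over non-missing calls; ``subset`` restricts to a row subset.
    """
    x = g.dosage if subset is None else g.dosage[np.asarray(subset, dtype=np.intp), :]
    with np.errstate(invalid="ignore"):
        alt = np.nanmean(x, axis=0) / 2.0
    ref_seen = np.nansum(2.0 - x, axis=0) > 0
    alt_seen = np.nansum(x, axis=0) > 0
    all_missing = np.isnan(x).all(axis=0)
    alt = np.where(all_missing, np.nan, alt)
    ref_seen &= ~all_missing
    alt_seen &= ~all_missing
    maf = np.minimum(alt, 1.0 - alt)
    return AlleleFrequencySet(maf=maf, alt_freq=alt,
                              allele_presence=np.column_stack([ref_seen, alt_seen]))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Read a genotype file in one of {vcf, plink_text, matrix_tsv}.

    Markers are returned sorted by (chrom, pos). Multi-allelic VCF records are
    skipped with a logged count; heterozygous calls map to dosage 1.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "vcf":
        g = _read_vcf(path)
    elif format == "plink_text":
        g = _read_plink_text(path)
    elif format == "matrix_tsv":
        g = _read_matrix_tsv(path)
    else:
        raise ValidationError(f"unknown format {format!r}")
    return g.sorted_by_map()


_GT_DOSE = {"0": 0.0, "1": 1.0, ".": np.nan}


def _read_vcf(path: Path) -> GenotypeMatrix:
    samples: list[str] = []
    marker_ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    rows: list[np.ndarray] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise IOError(f"malformed VCF record in {path}")
            alt = f[4]
            if "," in alt or alt == ".":
                skipped += 1
                continue
            fmt = f[8].split(":")
            try:
                gti = fmt.index("GT")
            except ValueError:
                raise IOError("VCF record without GT field")
            dos = np.empty(len(samples))
            for i, cell in enumerate(f[9:]):
                gt = cell.split(":")[gti]
                alleles = gt.replace("|", "/").split("/")
                vals = [_GT_DOSE.get(a) for a in alleles]
                if any(v is None for v in vals):
                    raise IOError(f"non-biallelic GT {gt!r}")
                dos[i] = np.nan if any(np.isnan(v) for v in vals) else sum(vals)
            name = f[2] if f[2] not in (".", "") else f"{f[0]}:{f[1]}"
            marker_ids.append(name)
            chroms.append(f[0])
            poss.append(int(f[1]))
            rows.append(dos)
    if skipped:
        logger.info("skipped %d multi-allelic VCF records", skipped)
    if not rows:
        raise ValidationError("zero biallelic markers in VCF")
    return GenotypeMatrix(samples, _dedup(marker_ids), np.array(chroms, dtype=object),
                          np.array(poss), np.column_stack(rows))


def _dedup(names: list[str]) -> list[str]:
    out, seen = [], {}
    for nm in names:
        if nm in seen:
            seen[nm] += 1
            nm = f"{nm}.{seen[nm]}"
        else:
            seen[nm] = 0
        out.append(nm)
    return out


def _read_plink_text(path: Path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map; `path` is the .ped (or prefix)."""
    ped = path if path.suffix == ".ped" else path.with_suffix(".ped")
    map_ = ped.with_suffix(".map")
    if not ped.exists() or not map_.exists():
        raise IOError(f"need both {ped} and {map_}")
    chroms, ids, poss = [], [], []
    for line in open(map_):
        f = line.split()
        if not f:
            continue
        chroms.append(f[0])
        ids.append(f[1])
        poss.append(int(f[3]))
    m = len(ids)
    samples, allele_rows = [], []
    for line in open(ped):
        f = line.split()
        if not f:
            continue
        if len(f) != 6 + 2 * m:
            raise IOError("ped line length inconsistent with map")
        samples.append(f[1])
        allele_rows.append(f[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(samples), m, 2)
    dosage = np.empty((len(samples), m))
    for j in range(m):
        a = alleles[:, j, :]
        observed = sorted({x for x in a.ravel() if x != "0"})
        if len(observed) > 2:
            raise ValidationError(f"marker {ids[j]} not biallelic")
        counted = observed[-1] if observed else None  # lexicographically larger allele
        miss = (a == "0").any(axis=1)
        dosage[:, j] = (a == counted).sum(axis=1)
        dosage[miss, j] = np.nan
    return GenotypeMatrix(samples, ids, np.array(chroms, dtype=object),
                          np.array(poss), dosage)


def _read_matrix_tsv(path: Path) -> GenotypeMatrix:
    """Dosage matrix: header of marker ids (optionally 'chrom:pos' encoded via
    two comment lines '#chrom' / '#pos'), first column accession id, cells in
    {0,1,2,NA}."""
    chrom_line = pos_line = None
    header = None
    samples, rows = [], []
    for line in open(path):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#chrom\t"):
            chrom_line = line.split("\t")[1:]
            continue
        if line.startswith("#pos\t"):
            pos_line = line.split("\t")[1:]
            continue
        cells = line.split("\t")
        if header is None:
            header = cells[1:]
            continue
        samples.append(cells[0])
        rows.append([np.nan if c in ("NA", "", ".") else float(c) for c in cells[1:]])
    if header is None or not rows:
        raise ValidationError("empty matrix file")
    m = len(header)
    chrom = np.array(chrom_line if chrom_line else ["1"] * m, dtype=object)
    pos = np.array([int(p) for p in pos_line] if pos_line else range(1, m + 1))
    return GenotypeMatrix(samples, header, chrom, pos, np.array(rows))


def write_matrix_tsv(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\t" + "\t".join(map(str, g.chrom)) + "\n")
        fh.write("#pos\t" + "\t".join(map(str, g.pos)) + "\n")
        fh.write("accession\t" + "\t".join(g.marker_ids) + "\n")
        for i, aid in enumerate(g.accession_ids):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in g.dosage[i]]
            fh.write(aid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_missingness(g: GenotypeMatrix, max_rate: float = 0.5) -> GenotypeMatrix:
    """Drop markers then accessions whose missing fraction exceeds max_rate.

    Marker pass runs first; accession missingness is recomputed on surviving
    markers.
    """
    if not (0.0 <= max_rate <= 1.0):
        raise ValidationError("max_rate must be in [0,1]")
    miss = np.isnan(g.dosage)
    keep_m = np.flatnonzero(miss.mean(axis=0) <= max_rate)
    if keep_m.size == 0:
        raise ValidationError("all markers removed by missingness filter")
    g = g.take_markers(keep_m)
    miss = np.isnan(g.dosage)
    keep_a = np.flatnonzero(miss.mean(axis=1) <= max_rate)
    if keep_a.size < 2:
        raise ValidationError("fewer than 2 accessions survive missingness filter")
    if keep_a.size < g.n:
        g = g.take_accessions(keep_a)
    return g


def impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by the marker's most frequent dosage (tie -> lower)."""
    x = g.dosage.copy()
    miss = np.isnan(x)
    if not miss.any():
        return g
    for j in np.flatnonzero(miss.any(axis=0)):
        col = x[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValidationError(f"marker {g.marker_ids[j]} fully missing")
        counts = np.array([(obs == v).sum() for v in (0.0, 1.0, 2.0)])
        mode = float(np.argmax(counts))  # argmax takes the first (lower) on ties
        col[np.isnan(col)] = mode
    return replace(g, dosage=x)


def filter_maf(g: GenotypeMatrix, min_maf: float = 0.01) -> GenotypeMatrix:
    """Keep markers with minor-allele frequency strictly above min_maf."""
    freq = allele_frequencies(g)
    keep = np.flatnonzero(freq.maf > min_maf)
    if keep.size == 0:
        raise ValidationError("all markers removed by MAF filter")
    return g.take_markers(keep)


def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.4) -> GenotypeMatrix:
    """Windowed LD pruning on squared Pearson correlation of dosages.

    Within each window of `window` markers (sliding by `step`, per chromosome),
    offending pairs (r^2 > r2_max) are resolved by removing the lower-MAF member
    (tie -> later position), deterministically, until no pair offends.
    """
    if window < 2:
        raise ValidationError("window must be >= 2")
    if not g.is_complete:
        raise ValidationError("ld_prune requires complete genotypes")
    maf = allele_frequencies(g).maf
    keep = np.ones(g.m, dtype=bool)
    chrom_str = g.chrom.astype(str)
    for c in g.chromosomes():
        cidx = np.flatnonzero(chrom_str == str(c))
        for start in range(0, len(cidx), step):
            widx = cidx[start:start + window]
            _prune_window(g.dosage, maf, keep, widx, r2_max)
            if start + window >= len(cidx):
                break
    return g.take_markers(np.flatnonzero(keep))


def _prune_window(dosage, maf, keep, widx, r2_max):
    active = [j for j in widx if keep[j]]
    while len(active) >= 2:
        x = dosage[:, active]
        sd = x.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x, rowvar=False)
        r2 = np.nan_to_num(r, nan=0.0) ** 2
        # constant columns correlate with nothing
        r2[sd == 0, :] = 0.0
        r2[:, sd == 0] = 0.0
        np.fill_diagonal(r2, 0.0)
        off = np.argwhere(np.triu(r2 > r2_max, k=1))
        if off.size == 0:
            return
        a, b = off[0]  # first offending pair in index order
        ja, jb = active[a], active[b]
        if maf[ja] < maf[jb]:
            drop = ja
        elif maf[jb] < maf[ja]:
            drop = jb
        else:
            drop = jb  # tie -> later position (windows are position-ordered)
        keep[drop] = False
        active.remove(drop)


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------


def rogers_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Rogers distance: mean over loci of |x_a - x_b| / 2."""
    if g.m == 0:
        raise ValidationError("no markers")
    if not g.is_complete:
        raise ValidationError("rogers_distance requires complete genotypes")
    from scipy.spatial.distance import pdist

    d = squareform(pdist(g.dosage, metric="cityblock") / (2.0 * g.m))
    return DistanceMatrix(list(g.accession_ids), d)


def kinship_vanraden(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix K = ZZ' / (2 sum p(1-p))."""
    if not g.is_complete:
        raise ValidationError("kinship requires complete genotypes")
    p = allele_frequencies(g).alt_freq
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValidationError("all markers monomorphic: VanRaden denominator is zero")
    Z = g.dosage - 2.0 * p
    K = (Z @ Z.T) / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(g.accession_ids), K)
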