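"""Core-collection construction: selection criteria, weighted multi-objective
scalarization and the four subset optimizers (random descent, simulated
annealing, hill climbing, genetic algorithm)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluation as ev
from .genotypes import (
    DistanceMatrix,
    GenotypeMatrix,
    KinshipMatrix,
    ValidationError,
)
from .structure import PCAResult

logger = logging.getLogger(__name__)

CRITERIA = ("ANE", "ENE", "HE", "SH", "CV", "CDmean", "AvgGRM", "Dopt")
# orientation: +1 if larger raw values are better, -1 if smaller are better
CRITERION_SIGN = {
    "ANE": -1, "ENE": +1, "HE": +1, "SH": +1, "CV": +1,
    "CDmean": +1, "AvgGRM": -1, "Dopt": +1,
}
OPTIMIZERS = ("random_descent", "local_search", "hill_climb", "genetic")
_DEFAULT_ITERS = {
    "random_descent": 3000,
    "local_search": 20000,
    "hill_climb": 3000,
    "genetic": 300,  # generations
}


@dataclass
class SelectionConfig:
    size: int
    criteria: list[tuple[str, float]]
    optimizer: str = "local_search"
    fixed_ids: list[str] = field(default_factory=list)
    seed: int = 0
    iterations: int | None = None
    restarts: int = 1
    lambda_ratio: float = 1.0  # sigma_e^2 / sigma_g^2 for CDmean
    dopt_axes: int | None = None
    ga_population: int = 40
    n_norm_subsets: int = 200  # bound-estimation sample for multi-objective

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZERS:
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")
        for name, w in self.criteria:
            if name not in CRITERIA:
                raise ValidationError(f"unknown criterion {name!r}")
            if w <= 0:
                raise ValidationError("criterion weights must be positive")
        total = sum(w for _, w in self.criteria)
        self.criteria = [(n, w / total) for n, w in self.criteria]

    @property
    def n_iterations(self) -> int:
        return self.iterations if self.iterations is not None \
            else _DEFAULT_ITERS[self.optimizer]


@dataclass
class CoreSelection:
    selected_ids: list[str]
    config: SelectionConfig
    objective_trace: list[float]
    final_value: float
    method_label: str = ""
    replicate: int = 0


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------


def crit_ane(d: DistanceMatrix, subset) -> float:
    """Accession-to-nearest-entry: mean over ALL accessions of the distance to
    the nearest selected entry (selected contribute 0). Lower is better."""
    idx = np.asarray(subset, dtype=np.intp)
    if idx.size == 0:
        raise ValidationError("subset must be non-empty")
    return float(d.d[:, idx].min(axis=1).mean())


def crit_ene(d: DistanceMatrix, subset) -> float:
    """Entry-to-nearest-entry: mean over entries of the distance to the closest
    other entry. Higher is better."""
    idx = np.asarray(subset, dtype=np.intp)
    if idx.size < 2:
        raise ValidationError("E-NE needs >= 2 entries")
    sub = d.submatrix(idx).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def crit_he(g: GenotypeMatrix, subset) -> float:
    return ev.eval_he(g, subset)


def crit_sh(g: GenotypeMatrix, subset) -> float:
    return ev.eval_sh(g, subset)


def crit_cv(g: GenotypeMatrix, subset) -> float:
    return ev.eval_cv(g, subset)


def crit_cdmean(K: KinshipMatrix, subset, lambda_ratio: float = 1.0) -> float:
    """Mean coefficient of determination of genotypic-value predictions for
    candidates outside the subset, under the mixed model with lambda =
    sigma_e^2/sigma_g^2.

    Evaluates CD_i = [K - lam*(Z'MZ + lam*K^-1)^-1]_ii / K_ii through the
    push-through identity, avoiding K^-1 (K is typically singular).
    """
    if lambda_ratio <= 0:
        raise ValidationError("lambda_ratio must be > 0")
    sel = np.asarray(subset, dtype=np.intp)
    Kf = K.K
    n = Kf.shape[0]
    out = np.setdiff1d(np.arange(n), sel)
    if out.size == 0:
        raise ValidationError("CDmean needs at least one unselected candidate")
    s = sel.size
    M = np.eye(s) - np.ones((s, s)) / s
    Kss = Kf[np.ix_(sel, sel)]
    Kns = Kf[:, sel]
    A = np.eye(s) + (Kss @ M) / lambda_ratio
    try:
        T = np.linalg.solve(A, Kf[sel, :] / lambda_ratio)  # s x n
    except np.linalg.LinAlgError:
        logger.warning("singular CDmean system; adding 1e-6 ridge")
        T = np.linalg.solve(A + 1e-6 * np.eye(s), Kf[sel, :] / lambda_ratio)
    # diag(lam * B^-1) = diag(K) - rowsum((K[:,sel] @ M) * T')
    lamBinv_diag = np.diag(Kf) - np.einsum("ij,ji->i", Kns @ M, T)
    kdiag = np.diag(Kf).copy()
    bad = kdiag <= 1e-12
    if bad.any():
        logger.warning("zero self-kinship encountered; adding 1e-6 ridge")
        kdiag[bad] = 1e-6
    cd = (kdiag - lamBinv_diag) / kdiag
    return float(cd[out].mean())


def crit_avg_grm(K: KinshipMatrix, subset) -> float:
    """Mean off-diagonal kinship within the subset. Lower is better."""
    idx = np.asarray(subset, dtype=np.intp)
    if idx.size < 2:
        raise ValidationError("Avg_GRM needs >= 2 entries")
    sub = K.submatrix(idx)
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def crit_dopt(p: PCAResult, subset, q: int) -> float:
    """Log-determinant of S'S with S the subset rows of the first q PC score
    columns; -inf for rank-deficient S."""
    idx = np.asarray(subset, dtype=np.intp)
    if idx.size < q:
        raise ValidationError("subset smaller than q")
    S = p.scores[idx, :q]
    sign, logdet = np.linalg.slogdet(S.T @ S)
    return float(logdet) if sign > 0 else -np.inf


# ---------------------------------------------------------------------------
# multi-objective scalarization
# ---------------------------------------------------------------------------


def combine_objectives(criteria, raw_values, bounds) -> float:
    """Map each raw criterion value to [0,1] with the supplied (min,max) bounds,
    flip minimization-type criteria so larger is always better, and return the
    weighted sum. Values outside the bounds are clamped (with a warning)."""
    total = 0.0
    wsum = sum(w for _, w in criteria)
    for (name, w), v in zip(criteria, raw_values):
        lo, hi = bounds[name]
        if not (np.isfinite(lo) and np.isfinite(hi)) or not lo < hi:
            raise ValidationError(f"bounds for {name} must be finite with min < max")
        if v < lo or v > hi:
            logger.debug("criterion %s value %.4g outside bounds [%g, %g]; clamped",
                         name, v, lo, hi)
        u = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
        if CRITERION_SIGN[name] < 0:
            u = 1.0 - u
        total += (w / wsum) * u
    return float(total)


# ---------------------------------------------------------------------------
# objective evaluator
# ---------------------------------------------------------------------------


class _Objective:
    """Callable mapping a subset (index array) to a scalar to MAXIMIZE.

    Genotype-based criteria are evaluated through vectorized per-subset
    statistics with whole-panel constants precomputed once; the public
    ``crit_*`` functions remain the reference implementations (equality is
    exercised in the test suite).
    """

    def __init__(self, g: GenotypeMatrix, aux: dict, cfg: SelectionConfig,
                 rng: np.random.Generator):
        self.g = g
        self.cfg = cfg
        self._X = g.dosage
        # whole-panel allele presence counts (1 or 2 per locus) for CV
        alt_seen = (self._X > 0).any(axis=0)
        ref_seen = (self._X < 2).any(axis=0)
        self._whole_alleles = np.maximum(
            alt_seen.astype(float) + ref_seen.astype(float), 1.0)
        self.d: DistanceMatrix | None = aux.get("distance")
        self.K: KinshipMatrix | None = aux.get("kinship")
        self.p: PCAResult | None = aux.get("pca")
        needed = {name for name, _ in cfg.criteria}
        if needed & {"ANE", "ENE"} and self.d is None:
            raise ValidationError("criteria require a DistanceMatrix in aux")
        if needed & {"CDmean", "AvgGRM"} and self.K is None:
            raise ValidationError("criteria require a KinshipMatrix in aux")
        if "Dopt" in needed and self.p is None:
            raise ValidationError("Dopt requires a PCAResult in aux")
        if "Dopt" in needed:
            q = cfg.dopt_axes
            if q is None:
                q = max(self.p.n_significant, 1)
            self.dopt_q = int(min(q, cfg.size - 1, self.p.scores.shape[1])) or 1
        self.bounds: dict[str, tuple[float, float]] | None = None
        if len(cfg.criteria) > 1:
            self._estimate_bounds(rng)

    def raw(self, name: str, subset: np.ndarray, x=None) -> float:
        if name == "ANE":
            return crit_ane(self.d, subset)
        if name == "ENE":
            return crit_ene(self.d, subset)
        if name == "CDmean":
            return crit_cdmean(self.K, subset, self.cfg.lambda_ratio)
        if name == "AvgGRM":
            return crit_avg_grm(self.K, subset)
        if name == "Dopt":
            return crit_dopt(self.p, subset, self.dopt_q)
        if x is None:
            x = self._X[np.asarray(subset, dtype=np.intp), :]
        if name == "HE":
            p = x.mean(axis=0) / 2.0
            return float(np.mean(1.0 - (p**2 + (1.0 - p) ** 2)))
        if name == "SH":
            p = x.mean(axis=0) / 2.0
            with np.errstate(divide="ignore", invalid="ignore"):
                e = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
                q = 1.0 - p
                e += np.where(q > 0, -q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
            return float(e.mean())
        if name == "CV":
            sub = (x > 0).any(axis=0).astype(float) + (x < 2).any(axis=0)
            return float(np.mean(np.minimum(sub, self._whole_alleles)
                                 / self._whole_alleles))
        raise ValidationError(f"unknown criterion {name!r}")

    def _estimate_bounds(self, rng: np.random.Generator) -> None:
        n, k = self.g.n, self.cfg.size
        vals: dict[str, list[float]] = {name: [] for name, _ in self.cfg.criteria}
        for _ in range(self.cfg.n_norm_subsets):
            subset = rng.choice(n, size=k, replace=False)
            for name in vals:
                v = self.raw(name, subset)
                if np.isfinite(v):
                    vals[name].append(v)
        self.bounds = {}
        for name, vs in vals.items():
            if not vs:
                self.bounds[name] = (0.0, 1.0)
                continue
            lo, hi = min(vs), max(vs)
            # optimized values travel far outside the random-subset range:
            # pad generously so the [0,1] clamp almost never flattens the
            # search landscape
            pad = 10.0 * (hi - lo) + 1e-6
            self.bounds[name] = (lo - pad, hi + pad)

    def __call__(self, subset: np.ndarray) -> float:
        idx = np.asarray(subset, dtype=np.intp)
        needs_x = any(name in ("HE", "SH", "CV") for name, _ in self.cfg.criteria)
        x = self._X[idx, :] if needs_x else None
        raws = [self.raw(name, idx, x=x) for name, _ in self.cfg.criteria]
        if len(self.cfg.criteria) == 1:
            return CRITERION_SIGN[self.cfg.criteria[0][0]] * raws[0]
        return combine_objectives(self.cfg.criteria, raws, self.bounds)


# ---------------------------------------------------------------------------
# optimizers (swap neighbourhood, fixed entries immovable)
# ---------------------------------------------------------------------------


def _swap(subset, pos, new_val):
    out = subset.copy()
    out[pos] = new_val
    return out


def _random_descent(obj, subset, free_mask, pool, iters, rng, trace):
    """Best of a sampled batch of swaps per iteration (steepest flavour)."""
    best = obj(subset)
    trace.append(best)
    free_pos = np.flatnonzero(free_mask)
    if free_pos.size == 0 or pool.size == 0:
        return subset, best
    batch = 8
    for _ in range(iters):
        cand_best, cand = best, None
        for _ in range(batch):
            pos = rng.choice(free_pos)
            repl = rng.choice(pool[~np.isin(pool, subset)])
            trial = _swap(subset, pos, repl)
            v = obj(trial)
            if v > cand_best:
                cand_best, cand = v, trial
        if cand is not None:
            subset, best = cand, cand_best
        trace.append(best)
    return subset, best


def _hill_climb(obj, subset, free_mask, pool, iters, rng, trace):
    """First-improvement single-swap hill climbing for exactly `iters` proposals."""
    best = obj(subset)
    trace.append(best)
    free_pos = np.flatnonzero(free_mask)
    if free_pos.size == 0 or pool.size == 0:
        return subset, best
    for _ in range(iters):
        pos = rng.choice(free_pos)
        repl = rng.choice(pool[~np.isin(pool, subset)])
        trial = _swap(subset, pos, repl)
        v = obj(trial)
        if v > best:
            subset, best = trial, v
        trace.append(best)
    return subset, best


def _local_search(obj, subset, free_mask, pool, iters, rng, trace,
                  t0=None, t_end_frac=1e-3):
    """Single-chain simulated annealing with geometric cooling."""
    cur_val = obj(subset)
    best, best_sub = cur_val, subset.copy()
    trace.append(best)
    free_pos = np.flatnonzero(free_mask)
    if free_pos.size == 0 or pool.size == 0:
        return subset, best
    # temperature scale from initial move deltas
    if t0 is None:
        deltas = []
        for _ in range(20):
            pos = rng.choice(free_pos)
            repl = rng.choice(pool[~np.isin(pool, subset)])
            deltas.append(abs(obj(_swap(subset, pos, repl)) - cur_val))
        t0 = max(float(np.mean(deltas)), 1e-8)
    cool = (t_end_frac) ** (1.0 / max(iters, 1))
    T = t0
    for _ in range(iters):
        pos = rng.choice(free_pos)
        repl = rng.choice(pool[~np.isin(pool, subset)])
        trial = _swap(subset, pos, repl)
        v = obj(trial)
        delta = v - cur_val
        if delta > 0 or rng.random() < np.exp(delta / T):
            subset, cur_val = trial, v
            if v > best:
                best, best_sub = v, subset.copy()
        T *= cool
        trace.append(best)
    return best_sub, best


def _genetic(obj, subset, free_mask, pool, generations, rng, trace,
             mu=40, fixed=None):
    """(mu+lambda) genetic algorithm: uniform subset crossover repaired to size
    k, swap mutation, elitist survival."""
    k = len(subset)
    fixed = np.asarray(fixed if fixed is not None else [], dtype=np.intp)
    n_free = k - len(fixed)
    free_pool = np.setdiff1d(pool, fixed)

    def make_random():
        pick = rng.choice(free_pool, size=n_free, replace=False)
        return np.concatenate([fixed, pick])

    popn = [subset.copy()] + [make_random() for _ in range(mu - 1)]
    fit = np.array([obj(s) for s in popn])
    order = np.argsort(fit)[::-1]
    popn = [popn[i] for i in order]
    fit = fit[order]
    trace.append(float(fit[0]))
    if n_free == 0:
        return popn[0], float(fit[0])
    for _ in range(generations):
        children = []
        for _ in range(mu):
            i, j = rng.choice(mu, size=2, replace=False)
            a = np.setdiff1d(popn[i], fixed)
            b = np.setdiff1d(popn[j], fixed)
            union = np.union1d(a, b)
            child = rng.choice(union, size=min(n_free, union.size), replace=False)
            if child.size < n_free:  # repair: top up from outside
                extra = rng.choice(np.setdiff1d(free_pool, child),
                                   size=n_free - child.size, replace=False)
                child = np.concatenate([child, extra])
            if rng.random() < 0.3:  # swap mutation
                out = np.setdiff1d(free_pool, child)
                if out.size:
                    child[rng.integers(child.size)] = rng.choice(out)
                    child = np.unique(child)
                    while child.size < n_free:
                        child = np.append(child, rng.choice(
                            np.setdiff1d(free_pool, child)))
            children.append(np.concatenate([fixed, child]))
        child_fit = np.array([obj(s) for s in children])
        all_pop = popn + children
        all_fit = np.concatenate([fit, child_fit])
        order = np.argsort(all_fit)[::-1][:mu]
        popn = [all_pop[i] for i in order]
        fit = all_fit[order]
        trace.append(float(fit[0]))
    return popn[0], float(fit[0])


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def optimize(g: GenotypeMatrix, aux: dict, cfg: SelectionConfig,
             method_label: str = "", replicate: int = 0) -> CoreSelection:
    """Run the configured optimizer from ``cfg.restarts`` random initial subsets
    (each containing the fixed set) and return the best CoreSelection found."""
    n = g.n
    if not (0 < cfg.size <= n):
        raise ValidationError(f"infeasible core size {cfg.size} for n={n}")
    fixed = g.index_of(cfg.fixed_ids) if cfg.fixed_ids else np.array([], dtype=np.intp)
    if len(fixed) > cfg.size:
        raise ValidationError("fixed set larger than core size")
    rng = np.random.default_rng(cfg.seed)
    objective = _Objective(g, aux, cfg, rng)
    pool = np.arange(n)
    free_pool = np.setdiff1d(pool, fixed)
    n_free = cfg.size - len(fixed)

    engines = {
        "random_descent": _random_descent,
        "local_search": _local_search,
        "hill_climb": _hill_climb,
    }
    best_sub, best_val = None, -np.inf
    trace: list[float] = []
    for _ in range(max(cfg.restarts, 1)):
        pick = rng.choice(free_pool, size=n_free, replace=False)
        init = np.concatenate([fixed, pick])
        free_mask = np.zeros(cfg.size, dtype=bool)
        free_mask[len(fixed):] = True
        sub_trace: list[float] = []
        if n_free == 0:
            sub, val = init, objective(init)
            sub_trace.append(val)
        elif cfg.optimizer == "genetic":
            sub, val = _genetic(objective, init, free_mask, pool,
                                cfg.n_iterations, rng, sub_trace,
                                mu=cfg.ga_population, fixed=fixed)
        else:
            sub, val = engines[cfg.optimizer](objective, init, free_mask, pool,
                                              cfg.n_iterations, rng, sub_trace)
        # global best-so-far trace stays non-decreasing across restarts
        running = max(best_val, -np.inf)
        for v in sub_trace:
            running = max(running, v)
            trace.append(running)
        if val > best_val:
            best_val, best_sub = val, sub
    best_sub = np.concatenate([fixed, np.sort(np.setdiff1d(best_sub, fixed))])
    selected_ids = [g.accession_ids[i] for i in best_sub]
    return CoreSelection(selected_ids=selected_ids, config=cfg,
                         objective_trace=trace, final_value=float(best_val),
                         method_label=method_label, replicate=replicate)


def replicate_selections(g: GenotypeMatrix, aux: dict, cfg: SelectionConfig,
                         n_rep: int = 10, base_seed: int | None = None,
                         method_label: str = "") -> list[CoreSelection]:
    """n_rep independent runs; replicate r uses seed base_seed + r."""
    if n_rep < 1:
        raise ValidationError("n_rep must be >= 1")
    if base_seed is None:
        base_seed = cfg.seed
    out = []
    for r in range(n_rep):
        from dataclasses import replace as dc_replace

        c = dc_replace(cfg, seed=base_seed + r, criteria=list(cfg.criteria))
        out.append(optimize(g, aux, c, method_label=method_label, replicate=r))
    return out


def selection_indices(g: GenotypeMatrix, sel: CoreSelection) -> np.ndarray:
    return g.index_of(sel.selected_ids)
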