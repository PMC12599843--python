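import numpy as np
import pandas as pd
import pytest

from corecollect import evaluation as ev
from corecollect import simulate
from corecollect import structure as st
from corecollect.genotypes import (
    DistanceMatrix,
    ValidationError,
    filter_maf,
    rogers_distance,
)

from conftest import make_g


def _g_from_freqs(freqs, n=10):
    """Panel whose column means hit the requested alt frequencies exactly."""
    cols = []
    for p in freqs:
        c = np.zeros(n)
        alt = int(round(2 * n * p))
        c[: alt // 2] = 2
        if alt % 2:
            c[alt // 2] = 1
        cols.append(c)
    return make_g(np.column_stack(cols))


# ---------------------------------------------------------------------------
# He / SH / MRD
# ---------------------------------------------------------------------------


def test_he_half_freq():
    g = _g_from_freqs([0.5, 0.5])
    assert ev.eval_he(g, range(g.n)) == pytest.approx(0.5)


def test_he_monomorphic():
    g = make_g(np.zeros((4, 3)))
    assert ev.eval_he(g, range(4)) == 0.0


def test_he_two_locus_arithmetic():
    g = _g_from_freqs([0.1, 0.3])
    assert ev.eval_he(g, range(g.n)) == pytest.approx(0.30)


def test_sh_examples():
    g = _g_from_freqs([0.5])
    assert ev.eval_sh(g, range(g.n)) == pytest.approx(1.0)
    g2 = make_g(np.full((4, 2), 2.0))
    assert ev.eval_sh(g2, range(4)) == 0.0
    g3 = _g_from_freqs([0.9])
    expected = -(0.9 * np.log2(0.9) + 0.1 * np.log2(0.1))
    assert ev.eval_sh(g3, range(g3.n)) == pytest.approx(expected)
    assert expected == pytest.approx(0.4690, abs=1e-4)


def test_mrd_examples():
    ids = ["a", "b", "c"]
    d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
    dm = DistanceMatrix(ids, d)
    assert ev.eval_mrd(dm, [0, 1, 2]) == pytest.approx(0.4)
    clone = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
    assert ev.eval_mrd(clone, [0, 1]) == 0.0
    with pytest.raises(ValidationError):
        ev.eval_mrd(dm, [0])


# ---------------------------------------------------------------------------
# RAR / CV / KL
# ---------------------------------------------------------------------------


def test_rar_whole_is_one(small_panel):
    g, _ = small_panel
    assert ev.eval_rar(g, range(g.n)) == 1.0


def test_rar_count_ratio():
    # 4 rare markers (1 alt copy in 20 = 0.025), subset keeps 3 segregating
    n = 10
    cols = []
    for j in range(4):
        c = np.zeros(n)
        c[j] = 1.0  # carriers are accessions 0..3
        cols.append(c)
    cols.append(np.tile([0.0, 2.0], n // 2))  # common marker
    g = make_g(np.column_stack(cols))
    subset = [0, 1, 2, 5, 6]  # carries rare alleles 0,1,2 but not 3
    assert ev.eval_rar(g, subset) == pytest.approx(0.75)


def test_rar_all_lost():
    n = 10
    c = np.zeros(n)
    c[0] = 1.0
    g = make_g(np.column_stack([c, np.tile([0.0, 2.0], 5)]))
    assert ev.eval_rar(g, [4, 5, 6]) == 0.0


def test_cv_examples(small_panel):
    g, _ = small_panel
    assert ev.eval_cv(g, range(g.n)) == 1.0


def test_cv_lost_minor_allele():
    # locus 0: subset keeps both alleles; locus 1: subset loses the minor
    g = make_g(np.column_stack([
        np.array([0, 2, 0, 2.0]),
        np.array([0, 0, 0, 2.0]),
    ]))
    assert ev.eval_cv(g, [0, 1, 2]) == pytest.approx(0.75)


def test_cv_monomorphic_locus_contributes_one():
    g = make_g(np.column_stack([np.zeros(4), np.array([0, 2, 0, 2.0])]))
    assert ev.eval_cv(g, [0, 1]) == pytest.approx(1.0)


def test_kl_whole_is_zero(small_panel):
    g, _ = small_panel
    assert ev.eval_kl(g, range(g.n)) == pytest.approx(0.0, abs=1e-12)


def test_kl_direct_evaluation():
    # whole: alt freq 0.1 over 10 accessions; subset of 5 with alt freq 0.2
    c = np.zeros(10)
    c[0] = c[1] = 1.0
    g = make_g(c.reshape(-1, 1))
    subset = [0, 1, 2, 3, 4]
    assert ev.eval_kl(g, subset) == pytest.approx(0.2 * np.log(2.0))


def test_kl_zero_iff_equal_frequencies():
    g = make_g(np.tile([0.0, 1.0, 2.0, 1.0], (4, 1)).T)
    # any subset with identical column means as whole -> 0
    assert ev.eval_kl(g, range(4)) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# COR
# ---------------------------------------------------------------------------


def test_cor_whole_is_one(small_panel):
    g, _ = small_panel
    p = st.pca_with_tw(g)
    if p.n_significant < 1:
        p.n_significant = 1
    assert ev.eval_cor(g, range(g.n), whole_pca=p) == pytest.approx(1.0, abs=1e-6)


def test_cor_sign_flip_invariant(small_panel):
    g, _ = small_panel
    p = st.pca_with_tw(g)
    p.n_significant = max(p.n_significant, 1)
    v1 = ev.eval_cor(g, range(0, g.n, 2), whole_pca=p)
    flipped = st.PCAResult(scores=-p.scores, loadings=-p.loadings,
                           eigenvalues=p.eigenvalues,
                           n_significant=p.n_significant)
    v2 = ev.eval_cor(g, range(0, g.n, 2), whole_pca=flipped)
    assert v1 == pytest.approx(v2, abs=1e-10)


def test_cor_monotone_in_subset_size():
    spec = simulate.PanelSpec(n_per_cluster=[70, 70, 60], fst=0.25, m=500,
                              n_chrom=3, seed=21)
    g, _ = simulate.generate_panel(spec)
    g = filter_maf(g, 0.01)
    p = st.pca_with_tw(g)
    p.n_significant = max(p.n_significant, 1)
    rng = np.random.default_rng(5)
    small, large = [], []
    for _ in range(5):
        small.append(ev.eval_cor(g, rng.choice(g.n, 20, replace=False), whole_pca=p))
        large.append(ev.eval_cor(g, rng.choice(g.n, 150, replace=False), whole_pca=p))
    assert np.mean(small) < np.mean(large)


# ---------------------------------------------------------------------------
# MD
# ---------------------------------------------------------------------------


def _trait_table(n=200):
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "cat1": rng.choice(["A", "B", "C"], n).astype(object),
        "quant1": rng.standard_normal(n),
    })
    return ev.TraitTable([f"a{i}" for i in range(n)], df)


def test_md_whole_is_zero():
    t = _trait_table()
    assert ev.eval_md(t, range(200)) == 0.0


def test_md_detects_excluded_binary_trait():
    n = 200
    rng = np.random.default_rng(1)
    binary = np.array(["yes"] * 100 + ["no"] * 100, dtype=object)
    df = pd.DataFrame({"flag": binary, "quant": rng.standard_normal(n)})
    t = ev.TraitTable([f"a{i}" for i in range(n)], df)
    subset = list(range(100, 160))  # all "no": the "yes" class is absent
    md = ev.eval_md(t, subset)
    assert md == pytest.approx(0.5)  # 1 of 2 traits significant


def test_md_duplicate_trait_dropped():
    n = 120
    rng = np.random.default_rng(2)
    c = rng.choice(["A", "B"], n).astype(object)
    df = pd.DataFrame({"c1": c, "c2": c.copy(),
                       "quant": rng.standard_normal(n)})
    t = ev.TraitTable([f"a{i}" for i in range(n)], df)
    # the duplicated categorical is removed: MD denominator is 2, not 3
    md = ev.eval_md(t, range(n), alpha=1.1)  # everything "significant"
    assert md == pytest.approx(1.0)
    md2 = ev.eval_md(t, range(n), alpha=-1.0)  # nothing significant
    assert md2 == 0.0


def test_cramers_v_bounds():
    rng = np.random.default_rng(3)
    a = pd.Series(rng.choice(list("AB"), 100))
    assert ev.cramers_v(a, a) == pytest.approx(1.0)
    b = pd.Series(rng.choice(list("CD"), 100))
    assert 0 <= ev.cramers_v(a, b) < 0.5


# ---------------------------------------------------------------------------
# composite index
# ---------------------------------------------------------------------------


def _report(**kw):
    base = dict(SH=0.7, He=0.2, MRD=0.4, RAR=1.0, CV=0.99, KL=0.01, COR=0.5,
                QTL=0.25)
    base.update(kw)
    return ev.EvaluationReport(**base)


def test_composite_identical_reports_zero():
    reports = [_report(), _report(), _report()]
    ev.composite_index(reports)
    assert all(r.I == 0.0 for r in reports)


def test_composite_dominating_report_max():
    reports = [
        _report(SH=0.75, He=0.25, RAR=1.0, CV=1.0, COR=0.7, KL=0.001, QTL=0.3),
        _report(SH=0.70, He=0.20, RAR=0.9, CV=0.98, COR=0.5, KL=0.01, QTL=0.2),
        _report(SH=0.65, He=0.18, RAR=0.8, CV=0.97, COR=0.4, KL=0.10, QTL=0.1),
    ]
    ev.composite_index(reports)
    assert reports[0].I == max(r.I for r in reports)


def test_composite_hand_arithmetic():
    reports = [_report(SH=0.6, KL=0.0), _report(SH=0.7, KL=0.1),
               _report(SH=0.8, KL=0.2)]
    ev.composite_index(reports)
    sh = np.array([0.6, 0.7, 0.8])
    kl = np.array([0.0, 0.1, 0.2])
    zsh = (sh - sh.mean()) / sh.std(ddof=1)
    zkl = (kl - kl.mean()) / kl.std(ddof=1)
    expected = (zsh - zkl) / 7.0  # other five components have zero variance
    for r, e in zip(reports, expected):
        assert r.I == pytest.approx(e, abs=1e-12)


def test_composite_affine_invariance():
    r1 = [_report(SH=0.6, QTL=0.1), _report(SH=0.8, QTL=0.3)]
    r2 = [_report(SH=0.6, QTL=0.1 * 3 + 5), _report(SH=0.8, QTL=0.3 * 3 + 5)]
    ev.composite_index(r1)
    ev.composite_index(r2)
    assert r1[0].I == pytest.approx(r2[0].I, abs=1e-12)


def test_composite_requires_qtl():
    reports = [_report(QTL=None), _report()]
    with pytest.raises(ValidationError):
        ev.composite_index(reports)
    ev.composite_index(reports, require_qtl=False)
    assert all(r.I is not None for r in reports)


def test_composite_needs_two_reports():
    with pytest.raises(ValidationError):
        ev.composite_index([_report()])


def test_report_table_layout():
    reports = [
        _report(), _report(SH=0.72),
    ]
    reports[0].method_label = reports[1].method_label = "SH_CV"
    reports[0].replicate, reports[1].replicate = 0, 1
    ev.composite_index(reports)
    tab = ev.report_table(reports)
    assert list(tab["method"]) == ["SH_CV"]
    assert tab["SH_mean"].iloc[0] == pytest.approx(0.71)


# ---------------------------------------------------------------------------
# criterion/metric consistency
# ---------------------------------------------------------------------------


def test_criteria_match_evaluation(small_panel):
    from corecollect import selection as sel

    g, _ = small_panel
    rng = np.random.default_rng(17)
    for _ in range(5):
        subset = rng.choice(g.n, 15, replace=False)
        assert sel.crit_he(g, subset) == pytest.approx(ev.eval_he(g, subset), abs=1e-12)
        assert sel.crit_sh(g, subset) == pytest.approx(ev.eval_sh(g, subset), abs=1e-12)
        assert sel.crit_cv(g, subset) == pytest.approx(ev.eval_cv(g, subset), abs=1e-12)


def test_objective_fast_paths_match_reference(small_panel):
    from corecollect import selection as sel
    from corecollect.genotypes import kinship_vanraden, rogers_distance

    g, _ = small_panel
    aux = {"distance": rogers_distance(g), "kinship": kinship_vanraden(g),
           "pca": st.pca_with_tw(g)}
    cfg = sel.SelectionConfig(size=15, criteria=[("SH", 0.4), ("CV", 0.3),
                                                 ("HE", 0.3)])
    rng = np.random.default_rng(3)
    obj = sel._Objective(g, aux, cfg, rng)
    for _ in range(5):
        subset = rng.choice(g.n, 15, replace=False)
        assert obj.raw("HE", subset) == pytest.approx(ev.eval_he(g, subset), abs=1e-12)
        assert obj.raw("SH", subset) == pytest.approx(ev.eval_sh(g, subset), abs=1e-12)
        assert obj.raw("CV", subset) == pytest.approx(ev.eval_cv(g, subset), abs=1e-12)
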