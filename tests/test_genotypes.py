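import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra.numpy import arrays

from corecollect.genotypes import (
    GenotypeMatrix,
    ValidationError,
    allele_frequencies,
    filter_maf,
    filter_missingness,
    impute_mode,
    kinship_vanraden,
    ld_prune,
    read_genotypes,
    rogers_distance,
    write_matrix_tsv,
)

from conftest import make_g


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


def test_read_vcf_gt_to_dosage(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        VCF_HEADER
        + "1\t100\tsnpA\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        + "1\t200\tsnpB\tC\tT\t.\t.\t.\tGT\t1|1\t0/0\t./.\n"
    )
    g = read_genotypes(vcf, "vcf")
    assert g.accession_ids == ["S1", "S2", "S3"]
    assert g.marker_ids == ["snpA", "snpB"]
    np.testing.assert_array_equal(g.dosage[:, 0], [0, 1, 2])
    assert g.dosage[0, 1] == 2 and g.dosage[1, 1] == 0
    assert np.isnan(g.dosage[2, 1])


def test_read_vcf_skips_multiallelic(tmp_path):
    vcf = tmp_path / "t.vcf"
    lines = [f"1\t{100 * (i + 1)}\ts{i}\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1"
             for i in range(5)]
    lines[2] = "1\t300\ts2\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1"
    vcf.write_text(VCF_HEADER + "\n".join(lines) + "\n")
    g = read_genotypes(vcf, "vcf")
    assert g.m == 4
    assert "s2" not in g.marker_ids


def test_read_vcf_all_multiallelic_errors(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(VCF_HEADER + "1\t100\ts0\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
    with pytest.raises(ValidationError):
        read_genotypes(vcf, "vcf")


def test_read_matrix_tsv_missing_cell(tmp_path):
    f = tmp_path / "m.tsv"
    f.write_text(
        "accession\ts1\ts2\n"
        "a1\t0\tNA\n"
        "a2\t2\t1\n"
    )
    g = read_genotypes(f, "matrix_tsv")
    assert np.isnan(g.dosage[0, 1])
    assert g.dosage[1, 0] == 2


def test_matrix_tsv_roundtrip(tmp_path):
    g = make_g([[0, 1, 2], [2, np.nan, 0]], chrom=["1", "1", "2"], pos=[5, 9, 3])
    write_matrix_tsv(g, tmp_path / "g.tsv")
    g2 = read_genotypes(tmp_path / "g.tsv", "matrix_tsv")
    assert g2.accession_ids == g.accession_ids
    # reader sorts by (chrom, pos): markers s1, s2 on chrom 1 then s3 on 2
    assert list(g2.chrom) == ["1", "1", "2"]
    np.testing.assert_array_equal(np.sort(g2.pos), [3, 5, 9])


def test_read_plink_text(tmp_path):
    (tmp_path / "p.map").write_text("1 m1 0 100\n1 m2 0 200\n")
    (tmp_path / "p.ped").write_text(
        "F1 I1 0 0 0 -9 A A A G\n"
        "F2 I2 0 0 0 -9 A G G G\n"
        "F3 I3 0 0 0 -9 G G 0 0\n"
    )
    g = read_genotypes(tmp_path / "p.ped", "plink_text")
    assert g.accession_ids == ["I1", "I2", "I3"]
    # counted allele is the lexicographically larger (G)
    np.testing.assert_array_equal(g.dosage[:, 0], [0, 1, 2])
    assert g.dosage[0, 1] == 1 and g.dosage[1, 1] == 2
    assert np.isnan(g.dosage[2, 1])


def test_missing_file_raises():
    with pytest.raises(IOError):
        read_genotypes("/nonexistent/file.vcf", "vcf")


def test_duplicate_accession_id_rejected():
    with pytest.raises(ValidationError):
        make_g([[0, 1], [1, 2]], ids=["a", "a"])


def test_invalid_dosage_rejected():
    with pytest.raises(ValidationError):
        make_g([[0, 3], [1, 2]])


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def test_filter_missingness_drops_bad_marker():
    d = np.zeros((4, 4))
    d[[0, 1, 2], 1] = np.nan  # marker 1 is 75% missing
    g = filter_missingness(make_g(d), 0.5)
    assert g.m == 3 and g.n == 4


def test_filter_missingness_identity_when_complete():
    g = make_g([[0, 1], [2, 0], [1, 1]])
    out = filter_missingness(g, 0.5)
    assert out.n == 3 and out.m == 2


def test_filter_missingness_drops_bad_accession():
    # accession 0 misses 3 of 4 markers (75%); each marker <= 25% missing
    d = np.zeros((4, 4))
    d[0, [0, 1, 2]] = np.nan
    g = filter_missingness(make_g(d), 0.5)
    assert g.m == 4 and g.n == 3
    assert "a0" not in g.accession_ids


def test_filter_missingness_marker_pass_first():
    # marker 0 is 60% missing; accession 0 is missing only at bad markers, so
    # dropping markers first rescues the accession
    d = np.zeros((5, 3))
    d[:3, 0] = np.nan
    d[0, 0] = np.nan
    g = filter_missingness(make_g(d), 0.5)
    assert g.m == 2 and g.n == 5


def test_impute_mode_examples():
    g = make_g([[0], [0], [2], [np.nan]] * 1)
    out = impute_mode(g)
    assert out.dosage[3, 0] == 0
    g2 = make_g([[0], [2], [np.nan]])
    assert impute_mode(g2).dosage[2, 0] == 0  # tie -> lower dosage
    g3 = make_g([[0, 1], [2, 1]])
    np.testing.assert_array_equal(impute_mode(g3).dosage, g3.dosage)


def test_impute_mode_fully_missing_marker_errors():
    g = make_g([[np.nan, 0], [np.nan, 1]])
    with pytest.raises(ValidationError):
        impute_mode(g)


def test_filter_maf_examples():
    n = 100
    col_rare = np.zeros(n)
    col_rare[0] = 1.0  # alt freq 0.005
    col_mono = np.zeros(n)
    col_keep = np.zeros(n)
    col_keep[:4] = 1.0  # alt freq 0.02
    g = make_g(np.column_stack([col_rare, col_mono, col_keep]))
    out = filter_maf(g, 0.01)
    assert out.marker_ids == ["s2"]


def test_filter_maf_all_removed_errors():
    g = make_g(np.zeros((4, 2)))
    with pytest.raises(ValidationError):
        filter_maf(g, 0.01)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _ld_panel(cols, **kw):
    return make_g(np.column_stack(cols), **kw)


def test_ld_prune_duplicate_pair():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 3, 30).astype(float)
    g = _ld_panel([a, a])
    out = ld_prune(g, window=10, step=5, r2_max=0.4)
    assert out.m == 1


def test_ld_prune_independent_identity():
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, (200, 6)).astype(float)
    g = make_g(d)
    r = np.corrcoef(d, rowvar=False) ** 2
    np.fill_diagonal(r, 0)
    assert r.max() < 0.4  # sanity of the fixture
    assert ld_prune(g, window=10, step=5, r2_max=0.4).m == 6


def test_ld_prune_fully_correlated_triple_keeps_one():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 2, 40).astype(float) * 2  # equal MAF, r^2 = 1 throughout
    g = _ld_panel([a, a, a])
    out = ld_prune(g, window=10, step=5, r2_max=0.4)
    assert out.m == 1
    assert out.marker_ids == ["s0"]  # ties drop the later position


def test_ld_prune_r2max_one_is_identity():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 3, 30).astype(float)
    g = _ld_panel([a, a, a])
    assert ld_prune(g, window=10, step=5, r2_max=1.0).m == 3


def test_ld_prune_window_too_small():
    g = make_g([[0, 1], [1, 2]])
    with pytest.raises(ValidationError):
        ld_prune(g, window=1)


def test_ld_prune_idempotent_single_window():
    rng = np.random.default_rng(4)
    base = rng.integers(0, 3, (50, 4)).astype(float)
    cols = [base[:, 0], base[:, 0], base[:, 1], base[:, 2], base[:, 3]]
    g = make_g(np.column_stack(cols))
    once = ld_prune(g, window=50, step=5, r2_max=0.4)
    twice = ld_prune(once, window=50, step=5, r2_max=0.4)
    assert once.marker_ids == twice.marker_ids


# ---------------------------------------------------------------------------
# Rogers distance & kinship
# ---------------------------------------------------------------------------


def test_rogers_examples():
    g = make_g([[0, 1, 2], [0, 1, 2]])
    assert rogers_distance(g).d[0, 1] == 0.0
    g2 = make_g([[0, 0], [2, 2]])
    assert rogers_distance(g2).d[0, 1] == 1.0
    g3 = make_g([[1], [2]])
    assert rogers_distance(g3).d[0, 1] == 0.5


def test_rogers_is_a_metric():
    rng = np.random.default_rng(7)
    g = make_g(rng.integers(0, 3, (10, 20)).astype(float))
    d = rogers_distance(g).d
    assert (d >= 0).all()
    np.testing.assert_allclose(d, d.T)
    np.testing.assert_allclose(np.diag(d), 0)
    n = d.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_kinship_identical_inbred_rows():
    g = make_g([[0, 2, 2], [0, 2, 2], [2, 0, 0], [1, 1, 2]])
    K = kinship_vanraden(g).K
    assert K[0, 1] == pytest.approx(K[0, 0])


def test_kinship_column_centering():
    rng = np.random.default_rng(8)
    g = make_g(rng.integers(0, 3, (6, 10)).astype(float))
    p = allele_frequencies(g).alt_freq
    Z = g.dosage - 2 * p
    np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
    K = kinship_vanraden(g).K
    ones = np.ones(6)
    assert abs(ones @ K @ ones) < 1e-8


def test_kinship_matches_double_loop_oracle():
    rng = np.random.default_rng(9)
    g = make_g(rng.integers(0, 3, (8, 15)).astype(float))
    p = g.dosage.mean(axis=0) / 2
    denom = 2 * np.sum(p * (1 - p))
    n = g.n
    expected = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            expected[i, j] = sum(
                (g.dosage[i, k] - 2 * p[k]) * (g.dosage[j, k] - 2 * p[k])
                for k in range(g.m)) / denom
    np.testing.assert_allclose(kinship_vanraden(g).K, expected, atol=1e-10)


def test_kinship_psd():
    rng = np.random.default_rng(10)
    g = make_g(rng.integers(0, 3, (9, 30)).astype(float))
    w = np.linalg.eigvalsh(kinship_vanraden(g).K)
    assert w.min() > -1e-8


def test_kinship_all_monomorphic_errors():
    g = make_g(np.full((3, 4), 2.0))
    with pytest.raises(ValidationError):
        kinship_vanraden(g)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

dosage_with_missing = arrays(
    np.float64, (6, 8),
    elements=hst.sampled_from([0.0, 1.0, 2.0, np.nan]),
)


@given(dosage_with_missing)
@settings(max_examples=30, deadline=None)
def test_missingness_filter_idempotent(d):
    try:
        once = filter_missingness(make_g(d), 0.5)
    except ValidationError:
        return
    twice = filter_missingness(once, 0.5)
    assert twice.marker_ids == once.marker_ids
    assert twice.accession_ids == once.accession_ids


@given(arrays(np.float64, (6, 8), elements=hst.sampled_from([0.0, 1.0, 2.0])))
@settings(max_examples=30, deadline=None)
def test_maf_filter_idempotent(d):
    try:
        once = filter_maf(make_g(d), 0.05)
    except ValidationError:
        return
    twice = filter_maf(once, 0.05)
    assert twice.marker_ids == once.marker_ids
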