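"""Genotype handling: allele frequencies, HWE, LD, EM phasing, moderators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxeds import (
    EmptySNPError,
    GenotypeTable,
    MonomorphicLocusError,
    SNPDef,
    allele_frequency,
    assign_haplotype_moderator,
    assign_snp_moderator,
    em_haplotype_frequencies,
    hwe_test,
    ld_pairwise,
)

from _oracles import two_snp_mle_grid
from conftest import SNP_DEFS, STUDY_DIPLOTYPES


# ---------------------------------------------------------------------------
# Allele frequency and HWE
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected",
    [
        ((39, 39, 8), 117 / 172),  # non-risk allele count / 2n
        ((10, 0, 0), 1.0),
        ((0, 0, 5), 0.0),
    ],
)
def test_allele_frequency(counts, expected):
    assert allele_frequency(counts) == pytest.approx(expected, abs=1e-12)


def test_allele_frequency_empty_snp_errors():
    with pytest.raises(EmptySNPError):
        allele_frequency((0, 0, 0))


def test_hwe_study_counts_conform():
    """The emulated study's genotype counts sit comfortably within HWE."""
    res = hwe_test((39, 39, 8))
    assert res.p_value == pytest.approx(0.697, abs=0.005)
    assert res.p_value > 0.05
    assert res.expected.sum() == pytest.approx(sum(res.observed))


def test_hwe_exact_proportions_give_zero_statistic():
    res = hwe_test((25, 50, 25))
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_hwe_total_heterozygote_deficit_rejected():
    assert hwe_test((50, 0, 50)).p_value < 1e-10


def test_hwe_monomorphic_degenerate_flagged():
    res = hwe_test((12, 0, 0))
    assert res.monomorphic and res.chi2 == 0.0 and res.p_value == 1.0


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    st.tuples(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    ).filter(lambda c: sum(c) > 0)
)
def test_hwe_invariant_under_allele_relabelling(counts):
    a = hwe_test(counts)
    b = hwe_test(counts[::-1])
    assert a.chi2 == pytest.approx(b.chi2, rel=1e-9, abs=1e-12)
    assert a.expected.sum() == pytest.approx(sum(counts))


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def test_ld_complete_disequilibrium():
    ld = ld_pairwise({"AB": 0.5, "ab": 0.5, "Ab": 0.0, "aB": 0.0})
    assert ld.d_prime == pytest.approx(1.0)
    assert ld.r_squared == pytest.approx(1.0)


def test_ld_linkage_equilibrium():
    ld = ld_pairwise({"AB": 0.18, "Ab": 0.42, "aB": 0.12, "ab": 0.28})
    assert ld.d_prime == pytest.approx(0.0, abs=1e-12)
    assert ld.r_squared == pytest.approx(0.0, abs=1e-12)


def test_ld_matches_direct_formula():
    f = {"AB": 0.4, "Ab": 0.2, "aB": 0.1, "ab": 0.3}
    p_a, p_b = 0.6, 0.5
    d = 0.4 - p_a * p_b
    ld = ld_pairwise(f)
    assert ld.r_squared == pytest.approx(d * d / (p_a * 0.4 * p_b * 0.5))
    assert ld.d_prime == pytest.approx(d / min(p_a * 0.5, 0.4 * 0.5))


def test_ld_monomorphic_marginal_is_distinct_error():
    with pytest.raises(MonomorphicLocusError):
        ld_pairwise({"AB": 0.7, "Ab": 0.3, "aB": 0.0, "ab": 0.0})


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4))
def test_ld_invariant_to_relabelling_and_bounded(weights):
    w = np.array(weights) / sum(weights)
    f = dict(zip(("AB", "Ab", "aB", "ab"), w))
    swapped = dict(zip(("aB", "ab", "AB", "Ab"), w))  # relabel locus 1
    a, b = ld_pairwise(f), ld_pairwise(swapped)
    assert a.d_prime == pytest.approx(b.d_prime, abs=1e-9)
    assert a.r_squared == pytest.approx(b.r_squared, abs=1e-9)
    assert 0 <= a.r_squared <= 1 and 0 <= a.d_prime <= 1


# ---------------------------------------------------------------------------
# EM haplotype estimation
# ---------------------------------------------------------------------------

TWO_SNPS = [SNPDef("snpA", "A", "C"), SNPDef("snpB", "G", "T")]


def _table(dosages, snps):
    ids = pd.Index([f"I{i}" for i in range(len(dosages))])
    cols = {s.rsid: [row[j] for row in dosages] for j, s in enumerate(snps)}
    return GenotypeTable(pd.DataFrame(cols, index=ids), snps)


def test_em_no_phase_ambiguity_single_haplotype():
    table = _table([(0, 0)] * 6, TWO_SNPS)
    est = em_haplotype_frequencies(table, seed=1)
    assert est.frequencies["AG"] == pytest.approx(1.0, abs=1e-9)
    assert (est.diplotypes["hap1"] == "AG").all()


def test_em_matches_exhaustive_grid_small_instance():
    dosages = [(0, 0), (2, 2), (1, 1), (1, 1), (0, 0)]
    table = _table(dosages, TWO_SNPS)
    est = em_haplotype_frequencies(table, seed=1)
    oracle = two_snp_mle_grid(dosages)  # order (00, 01, 10, 11)
    keys = ["AG", "AT", "CG", "CT"]
    for key, expected in zip(keys, oracle):
        assert est.frequencies[key] == pytest.approx(expected, abs=1e-3)
    # resolved phase: double heterozygotes pair the two observed homozygote
    # haplotypes
    assert est.frequencies["AG"] == pytest.approx(0.6, abs=1e-3)
    assert est.frequencies["CT"] == pytest.approx(0.4, abs=1e-3)


@pytest.mark.parametrize("case", range(4))
def test_em_matches_grid_oracle_random_small_instances(case, rng):
    dosages = [tuple(rng.integers(0, 3, size=2)) for _ in range(8)]
    table = _table(dosages, TWO_SNPS)
    est = em_haplotype_frequencies(table, seed=case)
    oracle = two_snp_mle_grid(dosages)
    got = np.array([est.frequencies[k] for k in ("AG", "AT", "CG", "CT")])
    # likelihood can be flat in a direction; compare attained likelihoods
    from _oracles import two_snp_loglik

    assert two_snp_loglik(got, dosages) >= two_snp_loglik(oracle, dosages) - 1e-6


def test_em_single_snp_reduces_to_allele_frequency():
    table = _table([(0,), (1,), (1,), (2,), (0,)], TWO_SNPS[:1])
    est = em_haplotype_frequencies(table, seed=1)
    assert est.frequencies["A"] == pytest.approx(0.6, abs=1e-9)
    assert est.frequencies["C"] == pytest.approx(0.4, abs=1e-9)


def test_em_loglik_monotone_and_converges(study_genotypes):
    est = em_haplotype_frequencies(
        study_genotypes, ["rs3800373", "rs9296158", "rs1360780"], seed=5
    )
    assert np.all(np.diff(est.loglik_trace) >= -1e-9)
    assert est.converged
    assert sum(est.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
    assert ((est.diplotypes["posterior"] >= 0) & (est.diplotypes["posterior"] <= 1)).all()


def test_em_all_missing_errors():
    ids = pd.Index(["a", "b"])
    frame = pd.DataFrame(
        {"snpA": [np.nan, np.nan], "snpB": [np.nan, np.nan]}, index=ids
    )
    table = GenotypeTable(frame, TWO_SNPS)
    with pytest.raises(EmptySNPError):
        em_haplotype_frequencies(table)


# ---------------------------------------------------------------------------
# Moderator groups
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rsid, expected",
    [
        ("rs3800373", (39, 47)),
        ("rs9296158", (39, 47)),
        ("rs1360780", (36, 50)),
        ("rs9470080", (35, 51)),
        ("rs4713916", (44, 42)),
    ],
)
def test_snp_moderator_group_sizes_match_study_table(study_genotypes, rsid, expected):
    grp = assign_snp_moderator(study_genotypes, rsid)
    assert grp.group_sizes == expected
    assert not grp.excluded_ids


def test_snp_moderator_missing_genotype_excluded():
    snps = [SNP_DEFS[0]]
    frame = pd.DataFrame(
        {"rs3800373": [0.0, 1.0, np.nan]}, index=pd.Index(["a", "b", "c"])
    )
    grp = assign_snp_moderator(GenotypeTable(frame, snps), "rs3800373")
    assert grp.excluded_ids == ["c"]
    assert grp.group_sizes == (1, 1)


def test_snp_moderator_unknown_coding_errors(study_genotypes):
    with pytest.raises(ValueError, match="coding"):
        assign_snp_moderator(study_genotypes, "rs3800373", coding="recessive")


def test_haplotype_moderator_from_em_reproduces_comparison_groups(study_genotypes):
    """Phasing the study-shaped table recovers the published comparison
    groups exactly: 41 reference, 42 risk-haplotype carriers, 3 excluded."""
    est = em_haplotype_frequencies(
        study_genotypes, ["rs3800373", "rs9296158", "rs1360780"], seed=7
    )
    grp = assign_haplotype_moderator(est)
    assert grp.group_sizes == (41, 42)
    assert len(grp.excluded_ids) == 3


@pytest.mark.parametrize(
    "pair, expected",
    [(("AGC", "CAT"), 1), (("AGC", "AAT"), 0), (("AAT", "CGC"), None)],
)
def test_haplotype_moderator_coding_rules(pair, expected):
    frame = pd.DataFrame(
        {"hap1": [pair[0]], "hap2": [pair[1]], "posterior": [1.0]},
        index=pd.Index(["x"]),
    )
    grp = assign_haplotype_moderator(frame)
    if expected is None:
        assert grp.excluded_ids == ["x"]
    else:
        assert grp.coding.loc["x"] == expected


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_genotype_csv_round_trip_and_allele_pairs(tmp_path, study_genotypes):
    path = tmp_path / "genotypes.csv"
    study_genotypes.to_csv(path)
    back = GenotypeTable.from_csv(path, SNP_DEFS)
    pd.testing.assert_frame_equal(back.dosages, study_genotypes.dosages)

    pairs = tmp_path / "pairs.csv"
    pairs.write_text(
        "individual_id,rs3800373\n" "a,A/A\n" "b,A/C\n" "c,C/C\n" "d,NA\n"
    )
    table = GenotypeTable.from_csv(pairs, SNP_DEFS[:1])
    assert list(table.dosage("rs3800373").fillna(-1)) == [0.0, 1.0, 2.0, -1.0]


def test_genotype_csv_rejects_undeclared_allele(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text("individual_id,rs3800373\na,G/G\n")
    with pytest.raises(ValueError, match="rs3800373"):
        GenotypeTable.from_csv(bad, SNP_DEFS[:1])


def test_minimal_vcf_reader(tmp_path):
    vcf = tmp_path / "mini.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=6>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
        "6\t100\trs3800373\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        "6\t200\trs9296158\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t./.\n"
    )
    table = GenotypeTable.from_vcf(vcf, SNP_DEFS[:2])
    assert list(table.dosage("rs3800373")) == [0.0, 1.0, 2.0]
    # REF is the risk allele here, so dosage is flipped relative to ALT count
    got = table.dosage("rs9296158")
    assert list(got[:2]) == [2.0, 1.0] and np.isnan(got.iloc[2])


def test_vcf_reader_rejects_mismatched_alleles(tmp_path):
    vcf = tmp_path / "bad.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=6>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "6\t100\trs3800373\tT\tG\t.\t.\t.\tGT\t0/1\n"
    )
    with pytest.raises(ValueError, match="strand"):
        GenotypeTable.from_vcf(vcf, SNP_DEFS[:1])


def test_snpdef_validation():
    with pytest.raises(ValueError):
        SNPDef("rs1", "A", "A")
    with pytest.raises(ValueError):
        SNPDef("rs1", "A", "X")
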