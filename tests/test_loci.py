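"""Locus calling, LD, interval gene lookup, eQTL scan, candidate ranking."""

import numpy as np
import pandas as pd
import pytest

from strainmap import loci as lc, mixedmodel as mm, synth
from strainmap.mixedmodel import AssociationResult
from strainmap.types import GeneAnnotation, NsSnpTable
from tests.conftest import make_panel


def _assoc(rows, trait="bmd"):
    t = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "maf",
                                    "n_used", "F", "P", "neglog10P"])
    return AssociationResult(table=t, trait=trait)


# ------------------------------------------------------------------- loci


def test_no_significant_snps_gives_no_loci():
    a = _assoc([("s1", "chr1", 100, 0.2, 10, 1.0, 0.5, 0.3)])
    assert lc.significant_loci(a) == []


def test_ci_is_peak_plus_minus_half_width():
    """A peak at 3.50 Mb with the default 1.3 Mb half-width spans
    [2.20, 4.80] Mb."""
    a = _assoc([("rs_peak", "chr12", 3_500_000, 0.13, 97, 30.0, 1.7e-6, 5.77)])
    (locus,) = lc.significant_loci(a)
    assert (locus.ci_start, locus.ci_end) == (2_200_000, 4_800_000)
    assert locus.ci_end - locus.ci_start == 2 * lc.DEFAULT_HALF_WIDTH_BP
    assert locus.peak_snp == "rs_peak"


def test_ci_clipped_at_chromosome_start_and_end():
    a = _assoc([("s1", "chr1", 500_000, 0.2, 10, 40.0, 1e-7, 7.0)])
    (locus,) = lc.significant_loci(a, chrom_lengths={"chr1": 1_400_000})
    assert locus.ci_start == 1                    # clipped at chrom start
    assert locus.ci_end == 1_400_000              # clipped at chrom length


def test_nearby_significant_snps_grouped_with_peak_by_score_then_position():
    a = _assoc([
        ("s1", "chr1", 2_000_000, 0.2, 10, 30.0, 1e-6, 6.0),
        ("s2", "chr1", 3_000_000, 0.2, 10, 40.0, 1e-7, 7.0),   # 1 Mb apart
        ("s3", "chr2", 3_000_000, 0.2, 10, 40.0, 1e-7, 7.0),
        ("s4", "chr2", 2_500_000, 0.2, 10, 40.0, 1e-7, 7.0),   # tie -> lower pos
    ])
    found = lc.significant_loci(a)
    assert len(found) == 2
    by_chrom = {l.chrom: l for l in found}
    assert by_chrom["chr1"].peak_snp == "s2"
    assert set(by_chrom["chr1"].member_snps) == {"s1", "s2"}
    assert by_chrom["chr2"].peak_snp == "s4"      # tie broken to lowest pos


def test_distant_snps_split_into_two_loci():
    a = _assoc([
        ("s1", "chr1", 1_000_000, 0.2, 10, 30.0, 1e-6, 6.0),
        ("s2", "chr1", 9_000_000, 0.2, 10, 40.0, 1e-7, 7.0),
    ])
    assert len(lc.significant_loci(a)) == 2


# --------------------------------------------------------------------- LD


def test_ld_r2_hand_cases():
    calls = np.array([
        [0, 0, 1, 0],
        [0, 1, 1, 1],
        [1, 0, 0, 0],
        [1, 1, 0, 1],
    ], dtype=float).T  # transpose: rows strains
    panel = make_panel(np.array([
        [0, 0, 1, 1],    # snp a over 4 strains
        [0, 1, 0, 1],    # snp b: orthogonal
        [1, 1, 0, 0],    # complement of a
        [0, 0, 1, 1],    # equal to a
    ]).T.astype(float))
    assert lc.ld_r2(panel, "s0", "s0") == pytest.approx(1.0)
    assert lc.ld_r2(panel, "s0", "s3") == pytest.approx(1.0)
    assert lc.ld_r2(panel, "s0", "s2") == pytest.approx(1.0)  # r = -1
    assert lc.ld_r2(panel, "s0", "s1") == pytest.approx(0.0)


def test_ld_r2_matches_haplotype_count_oracle(rng):
    """r^2 from the Pearson correlation equals the classic 2x2 haplotype
    frequency formula (pAB - pA pB)^2 / (pA(1-pA) pB(1-pB))."""
    for _ in range(20):
        calls = rng.integers(0, 2, size=(30, 2)).astype(float)
        if calls[:, 0].std() == 0 or calls[:, 1].std() == 0:
            continue
        panel = make_panel(calls)
        pa, pb = calls[:, 0].mean(), calls[:, 1].mean()
        pab = (calls[:, 0] * calls[:, 1]).mean()
        oracle = (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
        assert lc.ld_r2(panel, "s0", "s1") == pytest.approx(oracle, abs=1e-12)


def test_ld_r2_monomorphic_flagged_and_unknown_snp_error():
    panel = make_panel(np.array([[0, 0], [0, 1], [0, 1]], dtype=float))
    assert np.isnan(lc.ld_r2(panel, "s0", "s1"))
    with pytest.raises(KeyError):
        lc.ld_r2(panel, "nope", "s1")


def test_nonsyntenic_ld_flags_duplicated_column():
    calls = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [0, 0], [1, 1]],
                     dtype=float)
    panel = make_panel(calls, chrom=["chr1", "chr2"], pos=[100, 100])
    loci_list = [
        lc.Locus("bmd", "chr1", "s0", 100, 7.0, 0.5, 1, 200),
        lc.Locus("bmd", "chr2", "s1", 100, 6.0, 0.5, 1, 200),
    ]
    table = lc.nonsyntenic_ld_check(loci_list, panel)
    assert len(table) == 1
    assert table.iloc[0]["r2"] == pytest.approx(1.0)
    assert bool(table.iloc[0]["flagged"])
    # a single locus yields an empty table
    assert len(lc.nonsyntenic_ld_check(loci_list[:1], panel)) == 0


def test_nonsyntenic_flag_rate_near_zero_for_independent_snps(rng):
    calls = rng.integers(0, 2, size=(100, 40)).astype(float)
    panel = make_panel(calls, chrom=[f"chr{j % 4 + 1}" for j in range(40)],
                       pos=[1000 * (j + 1) for j in range(40)])
    loci_list = [lc.Locus("bmd", f"chr{j % 4 + 1}", f"s{j}", 1000 * (j + 1),
                          6.0, 0.5, 1, 10_000_000) for j in range(8)]
    table = lc.nonsyntenic_ld_check(loci_list, panel, r2_flag=0.4)
    assert table["flagged"].mean() < 0.05


# ------------------------------------------------------------------ genes


GENES = GeneAnnotation(pd.DataFrame({
    "gene_id": ["gA", "gB", "gC", "gD"],
    "chrom": ["chr1"] * 4,
    "txStart": [500, 1_900, 3_000, 9_000],
    "txEnd": [800, 2_100, 3_500, 9_500],
    "strand": ["+"] * 4,
}))


def test_genes_in_interval_any_overlap_rule():
    locus = lc.Locus("bmd", "chr1", "s1", 2_500, 6.0, 0.2, 2_000, 4_000)
    got = lc.genes_in_interval(GENES, locus)
    # gB straddles ci_start (included); gC inside; gA and gD outside
    assert list(got["gene_id"]) == ["gB", "gC"]
    empty = lc.Locus("bmd", "chr1", "s1", 100, 6.0, 0.2, 1, 400)
    assert len(lc.genes_in_interval(GENES, empty)) == 0


def test_genes_in_interval_monotone_in_half_width():
    counts = []
    for hw in [100, 500, 2_000, 5_000]:
        locus = lc.Locus("bmd", "chr1", "s1", 2_500, 6.0, 0.2,
                         2_500 - hw, 2_500 + hw)
        counts.append(len(lc.genes_in_interval(GENES, locus)))
    assert counts == sorted(counts)


def test_probe_snp_overlap_filter():
    panel = make_panel(np.zeros((2, 3)) + np.array([0., 1., 1.]),
                       pos=[150, 1_000, 5_000])
    probes = pd.DataFrame({
        "probe_id": ["p1", "p2", "p3"],
        "chrom": ["chr1"] * 3,
        "start": [100, 2_000, 4_990],
        "end": [200, 2_050, 5_040],
    })
    kept, removed = lc.probe_snp_overlap_filter(probes, panel)
    assert removed == 2                       # SNPs at 150 and 5000 overlap
    assert list(kept["probe_id"]) == ["p2"]
    kept2, removed2 = lc.probe_snp_overlap_filter(
        probes.assign(start=[20_000] * 3, end=[20_100] * 3), panel)
    assert removed2 == 0 and len(kept2) == 3
    with pytest.raises(ValueError, match="footprint"):
        lc.probe_snp_overlap_filter(probes.assign(start=[np.nan, 1, 2]), panel)


# ------------------------------------------------------------------- eQTL


def test_bonferroni_threshold_printed_value():
    """0.05 over 98 probes rounds to 5.1e-4 at two significant figures."""
    thr = lc.bonferroni_threshold(0.05, 98)
    assert float(f"{thr:.1e}") == 5.1e-4


def test_local_eqtl_scan_flags_planted_gene_and_null_rate():
    panel, truth = synth.simulate_panel(10, 40, 800, 2, seed=11)
    expr = synth.simulate_expression(panel, truth, n_genes=60, n_modules=3,
                                     within_cor=0.5,
                                     eqtl_effects={"n_eqtl": 4}, seed=11)
    genes = GeneAnnotation(truth.gene_table[
        ["gene_id", "chrom", "txStart", "txEnd", "strand"]].copy())
    K = mm.ibs_kinship(panel)
    hits = 0
    for gene, snp, _ in truth.eqtl_truth:
        row = genes.data[genes.data["gene_id"] == gene].iloc[0]
        center = (row.txStart + row.txEnd) // 2
        locus = lc.Locus("expr", str(row.chrom), snp, center, np.nan, np.nan,
                         max(1, center - 1_300_000), center + 1_300_000)
        recs = lc.local_eqtl_scan(expr, panel, locus, K, genes)
        mine = {r.gene_id: r for r in recs}
        assert gene in mine
        hits += int(mine[gene].significant)
    assert hits >= len(truth.eqtl_truth) - 1   # planted eQTLs detected

    # genes with no planted signal are rarely significant
    null_sig = 0
    n_null = 0
    planted = {g for g, _, _ in truth.eqtl_truth}
    row = genes.data.iloc[5]
    center = (row.txStart + row.txEnd) // 2
    locus = lc.Locus("expr", str(row.chrom), "x", center, np.nan, np.nan,
                     max(1, center - 1_300_000), center + 1_300_000)
    for rec in lc.local_eqtl_scan(expr, panel, locus, K, genes, alpha=0.05):
        if rec.gene_id not in planted:
            n_null += 1
            null_sig += int(rec.significant)
    assert n_null > 0 and null_sig <= max(1, 0.2 * n_null)


def test_local_eqtl_scan_empty_locus_warns(caplog):
    panel, truth = synth.simulate_panel(6, 10, 200, 2, seed=12)
    expr = synth.simulate_expression(panel, truth, n_genes=20, n_modules=2,
                                     within_cor=0.5,
                                     eqtl_effects={"n_eqtl": 0}, seed=12)
    genes = GeneAnnotation(truth.gene_table[
        ["gene_id", "chrom", "txStart", "txEnd", "strand"]].copy())
    K = mm.ibs_kinship(panel)
    # an interval on chr1 beyond any gene
    locus = lc.Locus("expr", "chr1", "x", 10, np.nan, np.nan, 1, 20)
    assert lc.local_eqtl_scan(expr, panel, locus, K, genes) == []


# -------------------------------------------------------------- candidates


def _simple_candidate_setup():
    calls = np.tile(np.array([[0, 1, 0, 1]], dtype=float).T, (1, 4))
    calls[:, 1] = [0, 1, 1, 0]
    panel = make_panel(calls, pos=[1_000, 2_000, 3_000, 4_000])
    genes = GeneAnnotation(pd.DataFrame({
        "gene_id": ["gE", "gN", "gB", "gOut"],
        "chrom": ["chr1"] * 4,
        "txStart": [900, 1_900, 2_900, 50_000],
        "txEnd": [1_100, 2_100, 3_100, 50_100],
        "strand": ["+"] * 4,
    }))
    locus = lc.Locus("bmd", "chr1", "s0", 1_000, 6.5, 0.25, 1, 5_000)
    return panel, genes, locus


def test_candidate_union_logic_and_ranking():
    """eQTL-only, NS-only and both-evidence genes all become candidates;
    the damaging-NS peak-coincident gene ranks first."""
    panel, genes, locus = _simple_candidate_setup()
    eqtls = [
        lc.EqtlRecord("p_gE", "gE", 1e-6, "s1", 4, 5.1e-4, True),
        lc.EqtlRecord("p_gB", "gB", 1e-5, "s2", 4, 5.1e-4, True),
        lc.EqtlRecord("p_gN", "gN", 0.9, "s3", 4, 5.1e-4, False),
    ]
    ns = NsSnpTable(pd.DataFrame({
        "snp_id": ["s0", "s1"],
        "chrom": ["chr1", "chr1"],
        "pos": [1_000, 2_000],
        "alleles": ["A/G", "A/G"],
        "gene_id": ["gE_other", "gN"],
        "effect_class": ["Benign", "Probably Damaging"],
        "aa_change": ["A1V", "F2S"],
    }))
    ns2 = NsSnpTable(pd.DataFrame({
        "snp_id": ["s0", "s1", "s2"],
        "chrom": ["chr1"] * 3,
        "pos": [1_000, 2_000, 3_000],
        "alleles": ["A/G"] * 3,
        "gene_id": ["gE", "gN", "gB"],
        "effect_class": ["Probably Damaging", "Possibly Damaging", "Benign"],
        "aa_change": ["A1V", "F2S", "K3R"],
    }))
    rep = lc.candidate_report(locus, eqtls, ns2, panel, genes)
    assert rep.n_candidates == 3
    t = rep.table.set_index("gene_id")
    assert bool(t.loc["gE", "peak_coincident"])       # damaging NS IS the peak
    assert rep.table.iloc[0]["gene_id"] == "gE"       # ranked first
    assert bool(t.loc["gE", "eqtl_significant"])
    assert bool(t.loc["gN", "ns_snp"] == "s1") and not t.loc["gN", "eqtl_significant"]
    assert bool(t.loc["gB", "eqtl_significant"]) and t.loc["gB", "ns_class"] is None
    # set algebra: candidates = eqtl-significant union damaging-NS
    assert set(t.index) == {"gE", "gB"} | {"gE", "gN"}


def test_candidate_report_empty_when_only_benign_and_no_eqtl():
    panel, genes, locus = _simple_candidate_setup()
    ns = NsSnpTable(pd.DataFrame({
        "snp_id": ["s1"], "chrom": ["chr1"], "pos": [2_000],
        "alleles": ["A/G"], "gene_id": ["gN"],
        "effect_class": ["Benign"], "aa_change": ["F2S"],
    }))
    rep = lc.candidate_report(locus, [], ns, panel, genes)
    assert rep.n_candidates == 0
    assert rep.funnel["genes_in_ci"] == 3
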