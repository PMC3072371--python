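"""Locus calling, LD checks, and candidate-gene prioritization.

A locus is a fixed-width confidence interval (peak SNP +/- half-width,
default 1.3 Mb for a 2.6 Mb interval) around the most significant SNP of a
group of genome-wide-significant SNPs. Candidate genes inside a locus are
prioritized by (a) a significant local eQTL for one of their probes or
(b) a damaging non-synonymous SNP, with LD (r^2) of each coding variant to
the peak SNP; a damaging coding SNP that *is* the peak SNP is the
strongest possible signal and ranks first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mixedmodel import AssociationResult, EigenContext, KinshipMatrix, reml_fit, _gls_at_delta
from .types import DAMAGING_CLASSES, ExpressionMatrix, GeneAnnotation, GenotypePanel, NsSnpTable

log = logging.getLogger("strainmap.loci")

GENOME_WIDE_NEGLOG10P = 5.39
DEFAULT_HALF_WIDTH_BP = 1_300_000


@dataclass
class Locus:
    trait: str
    chrom: str
    peak_snp: str
    peak_pos: int
    peak_neglog10p: float
    peak_maf: float
    ci_start: int
    ci_end: int
    member_snps: list = field(default_factory=list)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.ci_start <= pos <= self.ci_end


def significant_loci(assoc: AssociationResult,
                     threshold_neglog10: float = GENOME_WIDE_NEGLOG10P,
                     half_width_bp: int = DEFAULT_HALF_WIDTH_BP,
                     chrom_lengths: Optional[dict] = None) -> list[Locus]:
    """Group significant SNPs into fixed-width loci.

    SNPs within 2 * half_width of each other on one chromosome form one
    locus; the peak is the most significant SNP (ties -> lowest position);
    the confidence interval is peak +/- half_width clipped to
    [1, chromosome length].
    """
    t = assoc.table
    sig = t[t["neglog10P"] >= threshold_neglog10].sort_values(["chrom", "pos"])
    loci: list[Locus] = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        groups: list[list[int]] = []
        last_pos = None
        for idx, row in sub.iterrows():
            if last_pos is None or row["pos"] - last_pos > 2 * half_width_bp:
                groups.append([idx])
            else:
                groups[-1].append(idx)
            last_pos = row["pos"]
        for grp in groups:
            g = sub.loc[grp].sort_values(["neglog10P", "pos"],
                                         ascending=[False, True])
            # ties on score resolve to the lowest position
            top_score = g["neglog10P"].iloc[0]
            peak = g[g["neglog10P"] == top_score].sort_values("pos").iloc[0]
            lo = max(1, int(peak["pos"]) - half_width_bp)
            hi = int(peak["pos"]) + half_width_bp
            if chrom_lengths and str(chrom) in chrom_lengths:
                hi = min(hi, int(chrom_lengths[str(chrom)]))
            loci.append(Locus(
                trait=assoc.trait, chrom=str(chrom),
                peak_snp=str(peak["snp_id"]), peak_pos=int(peak["pos"]),
                peak_neglog10p=float(peak["neglog10P"]),
                peak_maf=float(peak["maf"]),
                ci_start=lo, ci_end=hi,
                member_snps=list(sub.loc[grp, "snp_id"]),
            ))
    loci.sort(key=lambda l: (l.chrom, l.peak_pos))
    log.info("significant loci: %d at -log10P >= %.3g", len(loci),
             threshold_neglog10)
    return loci


# ------------------------------------------------------------------- LD

def ld_r2(panel: GenotypePanel, snp_a: str, snp_b: str,
          strain_subset: Optional[Sequence[str]] = None) -> float:
    """Squared Pearson correlation of 0/1 calls over jointly typed strains.

    Returns NaN when either SNP is monomorphic within the subset.
    """
    ja = panel.snp_index(snp_a)
    jb = panel.snp_index(snp_b)
    G = panel.calls
    if strain_subset is not None:
        rows = [panel.strain_index(s) for s in strain_subset]
        G = G[rows, :]
    a, b = G[:, ja], G[:, jb]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def nonsyntenic_ld_check(loci: list[Locus], panel: GenotypePanel,
                         r2_flag: float = 0.4,
                         strain_subset: Optional[Sequence[str]] = None
                         ) -> pd.DataFrame:
    """r^2 between peak SNPs of locus pairs on different chromosomes.

    Pairs at r^2 >= r2_flag are flagged as potential non-syntenic
    (breeding-history) artifacts.
    """
    rows = []
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i], loci[j]
            if a.chrom == b.chrom:
                continue
            r2 = ld_r2(panel, a.peak_snp, b.peak_snp, strain_subset)
            rows.append((a.peak_snp, a.chrom, b.peak_snp, b.chrom, r2,
                         bool(np.isfinite(r2) and r2 >= r2_flag)))
    return pd.DataFrame(rows, columns=["snp_a", "chrom_a", "snp_b", "chrom_b",
                                       "r2", "flagged"])


# ------------------------------------------------------------------- genes

def genes_in_interval(annotation: GeneAnnotation, locus: Locus) -> pd.DataFrame:
    """Genes whose [txStart, txEnd] overlaps the locus CI by >= 1 bp,
    sorted by txStart."""
    d = annotation.data
    hit = d[(d["chrom"] == locus.chrom) &
            (d["txStart"] <= locus.ci_end) &
            (d["txEnd"] >= locus.ci_start)]
    out = hit.sort_values("txStart").reset_index(drop=True)
    log.info("locus %s:%d-%d contains %d gene(s)", locus.chrom,
             locus.ci_start, locus.ci_end, len(out))
    return out


def probe_snp_overlap_filter(probes: pd.DataFrame,
                             panel: GenotypePanel) -> tuple[pd.DataFrame, int]:
    """Drop probes whose genomic footprint contains any panel SNP
    (hybridization-artifact guard). Returns (kept, n_removed)."""
    required = {"probe_id", "chrom", "start", "end"}
    if not required <= set(probes.columns):
        raise ValueError(f"probe table needs columns {sorted(required)}")
    if probes[["start", "end"]].isna().any().any():
        raise ValueError("probe without genomic footprint")
    keep = []
    for _, row in probes.iterrows():
        on_c = panel.chrom == row["chrom"]
        overlap = ((panel.pos[on_c] >= row["start"]) &
                   (panel.pos[on_c] <= row["end"])).any()
        keep.append(not overlap)
    kept = probes[np.asarray(keep)].reset_index(drop=True)
    n_removed = len(probes) - len(kept)
    if n_removed:
        log.info("probe/SNP overlap filter removed %d of %d probes",
                 n_removed, len(probes))
    return kept, n_removed


# ------------------------------------------------------------------- eQTL

@dataclass
class EqtlRecord:
    probe_id: str
    gene_id: str
    min_p: float
    best_snp: str
    n_snps_tested: int
    bonferroni_threshold: float
    significant: bool


def bonferroni_threshold(alpha: float, n_probes: int) -> float:
    if n_probes <= 0:
        raise ValueError("n_probes must be positive")
    return alpha / n_probes


def local_eqtl_scan(expr: ExpressionMatrix, panel: GenotypePanel,
                    locus: Locus, K: KinshipMatrix,
                    annotation: GeneAnnotation, alpha: float = 0.05,
                    n_probes_total: Optional[int] = None,
                    maf_min: float = 0.05) -> list[EqtlRecord]:
    """Mixed-model association of every locus probe with every locus SNP.

    Probes are those of genes overlapping the locus CI that survive the
    probe/SNP overlap filter; SNPs are restricted to the CI. Per probe, the
    minimum P is compared against alpha / n_probes_tested (Bonferroni; by
    default the count of probes in this call, or pass the run-wide total).
    Expression is strain-level (one array per strain), so the incidence is
    the identity and the EMMAX-style approximation (null-model delta per
    probe) scores each SNP.
    """
    locus_genes = genes_in_interval(annotation, locus)
    probes = expr.probe_annotation[
        expr.probe_annotation["gene_symbol"].isin(locus_genes["gene_id"])
    ].reset_index(drop=True)
    probes, _ = probe_snp_overlap_filter(probes, panel)
    if len(probes) == 0:
        log.warning("locus %s:%d-%d has zero usable probes", locus.chrom,
                    locus.ci_start, locus.ci_end)
        return []
    n_probes = n_probes_total if n_probes_total is not None else len(probes)
    thr = bonferroni_threshold(alpha, n_probes)

    maf = panel.maf()
    in_ci = ((panel.chrom == locus.chrom) & (panel.pos >= locus.ci_start) &
             (panel.pos <= locus.ci_end) & (np.nan_to_num(maf) >= maf_min))
    snp_idx = np.flatnonzero(in_ci)
    if snp_idx.size == 0:
        log.warning("locus %s:%d-%d has zero SNPs after filters", locus.chrom,
                    locus.ci_start, locus.ci_end)
        return []

    # strains present on the array, in panel order
    strains = [s for s in panel.strain_ids
               if s in set(expr.sample_strains.values)]
    sample_of = {v: k for k, v in expr.sample_strains.items()}
    cols = [sample_of[s] for s in strains]
    rows_idx = [panel.strain_index(s) for s in strains]
    G = panel.calls[rows_idx][:, snp_idx]
    Ksub = K.subset(strains)
    Z = np.eye(len(strains))
    eig = EigenContext.build(Z, Ksub.values)
    X0 = np.ones((len(strains), 1))

    records = []
    for _, prow in probes.iterrows():
        y = expr.values.loc[prow["probe_id"], cols].to_numpy(float)
        null = reml_fit(y, X0, eig=eig)
        best_p, best_snp = np.inf, None
        for local_j, j in enumerate(snp_idx):
            g = G[:, local_j]
            ok = ~np.isnan(g)
            if g[ok].std() == 0:
                continue
            if ok.all():
                X = np.column_stack([np.ones(len(strains)), g])
                fit = _gls_at_delta(y, X, eig, null.delta)
                F, P = fit.wald_f(1)
            else:
                Zs = np.eye(int(ok.sum()))
                eig_s = EigenContext.build(Zs, Ksub.values[np.ix_(ok, ok)])
                X = np.column_stack([np.ones(int(ok.sum())), g[ok]])
                fit = reml_fit(y[ok], X, eig=eig_s)
                F, P = fit.wald_f(1)
            if P < best_p:
                best_p, best_snp = P, str(panel.snp_ids[j])
        records.append(EqtlRecord(
            probe_id=str(prow["probe_id"]), gene_id=str(prow["gene_symbol"]),
            min_p=float(best_p), best_snp=best_snp,
            n_snps_tested=int(snp_idx.size),
            bonferroni_threshold=thr,
            significant=bool(best_p <= thr),
        ))
    return records


# -------------------------------------------------------------- candidates

@dataclass
class CandidateReport:
    locus: Locus
    table: pd.DataFrame            # one row per functional candidate, ranked
    n_genes: int
    n_candidates: int
    funnel: dict


def candidate_report(locus: Locus, eqtl_records: list[EqtlRecord],
                     ns_table: NsSnpTable, panel: GenotypePanel,
                     annotation: GeneAnnotation,
                     known_genes: Optional[Sequence[str]] = None,
                     ld_strains: Optional[Sequence[str]] = None) -> CandidateReport:
    """Functional candidates: significant local eQTL OR a damaging coding
    SNP inside the locus; damaging SNPs carry r^2 to the peak SNP and a
    peak-coincidence flag. Ranking: peak-coincident damaging variants
    first, then by r^2 to peak, then eQTL strength."""
    known = set(known_genes or [])
    locus_genes = genes_in_interval(annotation, locus)
    gene_ids = set(locus_genes["gene_id"])

    eqtl_by_gene: dict[str, EqtlRecord] = {}
    for rec in eqtl_records:
        if rec.gene_id in gene_ids:
            prev = eqtl_by_gene.get(rec.gene_id)
            if prev is None or rec.min_p < prev.min_p:
                eqtl_by_gene[rec.gene_id] = rec

    ns_in = ns_table.data[
        (ns_table.data["chrom"] == locus.chrom) &
        (ns_table.data["pos"] >= locus.ci_start) &
        (ns_table.data["pos"] <= locus.ci_end) &
        (ns_table.data["gene_id"].isin(gene_ids))
    ]
    damaging_in = ns_in[ns_in["effect_class"].isin(DAMAGING_CLASSES)]

    rows = []
    candidates = set(g for g, r in eqtl_by_gene.items() if r.significant) | \
        set(damaging_in["gene_id"])
    for gene in sorted(candidates):
        erec = eqtl_by_gene.get(gene)
        gene_ns = damaging_in[damaging_in["gene_id"] == gene]
        best_r2, best_snp, best_class, coincident = np.nan, None, None, False
        for _, srow in gene_ns.iterrows():
            is_peak = srow["snp_id"] == locus.peak_snp
            r2 = 1.0 if is_peak else ld_r2(panel, srow["snp_id"],
                                           locus.peak_snp, ld_strains)
            if is_peak or (np.isnan(best_r2) or
                           (np.isfinite(r2) and r2 > best_r2)):
                best_r2, best_snp = r2, str(srow["snp_id"])
                best_class = str(srow["effect_class"])
                coincident = coincident or is_peak
        rows.append({
            "gene_id": gene,
            "eqtl_min_p": erec.min_p if erec else np.nan,
            "eqtl_significant": bool(erec.significant) if erec else False,
            "ns_snp": best_snp,
            "ns_class": best_class,
            "r2_to_peak": best_r2,
            "peak_coincident": coincident,
            "known_gene": gene in known,
        })
    table = pd.DataFrame(rows, columns=[
        "gene_id", "eqtl_min_p", "eqtl_significant", "ns_snp", "ns_class",
        "r2_to_peak", "peak_coincident", "known_gene"])
    if len(table):
        table = table.sort_values(
            by=["peak_coincident", "r2_to_peak", "eqtl_significant", "gene_id"],
            ascending=[False, False, False, True],
            na_position="last",
        ).reset_index(drop=True)
    funnel = {
        "genes_in_ci": len(locus_genes),
        "genes_with_probe": len(eqtl_by_gene),
        "eqtl_significant_genes": int(sum(r.significant
                                          for r in eqtl_by_gene.values())),
        "damaging_ns_genes": int(damaging_in["gene_id"].nunique()),
        "functional_candidates": len(table),
    }
    log.info("candidate funnel %s", funnel)
    return CandidateReport(locus=locus, table=table,
                           n_genes=len(locus_genes),
                           n_candidates=len(table), funnel=funnel)
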