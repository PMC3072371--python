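"""Self-contained recovery and calibration experiments on synthetic panels.

Each experiment simulates a dataset with known ground truth, runs the
relevant pipeline stage, and scores recovery. They are the package's own
benchmark suite: deterministic given a seed, and sized for a desk machine.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import coexnet, loci as loci_mod, mixedmodel as mm, synth


def null_calibration(seed: int = 0, n_snps: int = 1000,
                     n_pheno_draws: int = 6, alpha: float = 0.01) -> dict:
    """Type-I error and genomic inflation of the mixed model on a
    structured panel under the polygenic null, against naive strain-mean
    OLS on the same data.

    The phenotype has no causal SNP (causal_frac = 0) but keeps the
    polygenic term, so every SNP is null while the trait still tracks
    strain relatedness -- the confounding the mixed model exists to absorb.
    The scan uses the whole-genome kinship (loco=False): calibration under
    a polygenic null is the property of modeling *all* background signal
    through K, whereas leave-one-chromosome-out deliberately leaves the
    focal chromosome's background unmodeled to regain power.
    """
    cfg = replace(synth.ScenarioConfig(), n_snps=n_snps, causal_frac=0.0)
    panel, truth = synth.simulate_panel(
        cfg.n_classical, cfg.n_ri, cfg.n_snps, cfg.n_chrom, seed,
        n_ancestral=cfg.n_ancestral, block_snps=cfg.block_snps,
        n_groups=cfg.n_groups, structure_strength=cfg.structure_strength,
        mean_crossovers=cfg.mean_crossovers)
    K = mm.ibs_kinship(panel, mm.snp_filters(panel).mask)
    p_mm, p_ols = [], []
    for draw in range(n_pheno_draws):
        pheno = synth.simulate_phenotypes(panel, truth, cfg.reps_per_strain,
                                          cfg.h2, 0.0,
                                          seed=seed * 1000 + draw,
                                          trait=cfg.trait)
        res = mm.genome_scan(pheno, panel, K, cfg.trait, mode="exact",
                             loco=False)
        tab = res.table.dropna(subset=["P"])
        p_mm.extend(tab["P"].tolist())

        means = pheno.trait_frame(cfg.trait).groupby("strain_id")["value"] \
            .mean().reindex(panel.strain_ids).to_numpy()
        maf_mask = mm.snp_filters(panel).mask
        s = panel.n_strains
        for j in np.flatnonzero(maf_mask):
            x = panel.calls[:, j]
            if np.isnan(x).any() or x.std() == 0:
                continue
            r = np.corrcoef(x, means)[0, 1]
            F = r * r / max(1.0 - r * r, 1e-12) * (s - 2)
            p_ols.append(float(stats.f.sf(F, 1, s - 2)))
    p_mm = np.asarray(p_mm)
    p_ols = np.asarray(p_ols)
    return {
        "n_tests": int(p_mm.size),
        "type1_mm": float(np.mean(p_mm <= alpha)),
        "type1_ols": float(np.mean(p_ols <= alpha)),
        "lambda_mm": mm.genomic_inflation(p_mm),
        "lambda_ols": mm.genomic_inflation(p_ols),
    }


def causal_recovery(seed: int = 0,
                    config: Optional[synth.ScenarioConfig] = None,
                    threshold: float = loci_mod.GENOME_WIDE_NEGLOG10P) -> dict:
    """One end-to-end run: simulate, scan, call loci, eQTL-scan, rank
    candidates; report whether the planted SNP/gene were recovered."""
    ds = synth.simulate_scenario(config, seed=seed)
    res = mm.genome_scan(ds.phenotypes, ds.panel, None, ds.config.trait,
                         mode="exact", loco=True)
    tab = res.table.dropna(subset=["neglog10P"])
    top = tab.loc[tab["neglog10P"].idxmax()]
    top_is_causal = bool(top["snp_id"] == ds.truth.causal_snp_id)
    top_above = bool(top["neglog10P"] >= threshold)
    cj = ds.panel.snp_index(ds.truth.causal_snp_id)
    top_in_locus = bool(
        str(top["chrom"]) == str(ds.panel.chrom[cj]) and
        abs(int(top["pos"]) - int(ds.panel.pos[cj]))
        <= loci_mod.DEFAULT_HALF_WIDTH_BP)
    crow = tab[tab["snp_id"] == ds.truth.causal_snp_id]
    causal_nlp = float(crow["neglog10P"].iloc[0]) if len(crow) else float("nan")

    found = loci_mod.significant_loci(res, threshold_neglog10=threshold,
                                      chrom_lengths=ds.panel.chrom_lengths())
    K = mm.ibs_kinship(ds.panel, mm.snp_filters(ds.panel).mask)
    classical = [s for s in ds.panel.strain_ids if str(s).startswith("C")]
    n_total = 0
    for locus in found:
        lg = loci_mod.genes_in_interval(ds.genes, locus)
        pr = ds.expression.probe_annotation[
            ds.expression.probe_annotation["gene_symbol"].isin(lg["gene_id"])]
        pr, _ = loci_mod.probe_snp_overlap_filter(pr.reset_index(drop=True),
                                                  ds.panel)
        n_total += len(pr)
    best_gene, best_key = None, None
    for locus in found:
        recs = loci_mod.local_eqtl_scan(ds.expression, ds.panel, locus, K,
                                        ds.genes,
                                        n_probes_total=n_total or None)
        rep = loci_mod.candidate_report(locus, recs, ds.ns_snps, ds.panel,
                                        ds.genes, ld_strains=classical)
        if len(rep.table):
            cand = rep.table.iloc[0]
            key = (bool(cand["peak_coincident"]), locus.peak_neglog10p)
            if best_key is None or key > best_key:
                best_key, best_gene = key, str(cand["gene_id"])
    return {
        "top_is_causal": top_is_causal,
        "top_in_causal_locus": top_in_locus,
        "top_neglog10p": float(top["neglog10P"]),
        "causal_neglog10p": causal_nlp,
        "causal_above_threshold": bool(causal_nlp >= threshold),
        "top_above_threshold": top_above,
        "n_loci": len(found),
        "candidate_gene": best_gene,
        "candidate_is_causal": bool(best_gene == ds.truth.causal_gene),
        "causal_snp": ds.truth.causal_snp_id,
        "causal_gene": ds.truth.causal_gene,
    }


def causal_recovery_rate(n_seeds: int = 20, seed0: int = 0,
                         config: Optional[synth.ScenarioConfig] = None) -> dict:
    """Fraction of seeds where the planted SNP is the top scan SNP above
    the genome-wide threshold and its gene is the top-ranked candidate."""
    runs = [causal_recovery(seed0 + i, config) for i in range(n_seeds)]
    full = [r["top_is_causal"] and r["top_above_threshold"] and
            r["candidate_is_causal"] for r in runs]
    return {
        "n_seeds": n_seeds,
        "rate_top_snp": float(np.mean([r["top_is_causal"] and
                                       r["top_above_threshold"]
                                       for r in runs])),
        "rate_causal_above_threshold": float(np.mean(
            [r["causal_above_threshold"] for r in runs])),
        "rate_top_in_causal_locus": float(np.mean(
            [r["top_in_causal_locus"] and r["top_above_threshold"]
             for r in runs])),
        "rate_candidate_gene": float(np.mean([r["candidate_is_causal"]
                                              for r in runs])),
        "rate_full_recovery": float(np.mean(full)),
        "runs": runs,
    }


def module_recovery(seed: int = 0, n_genes: int = 600, n_modules: int = 5,
                    within_cor: float = 0.7) -> float:
    """Adjusted Rand index between detected modules and planted truth for
    the default modular expression scenario."""
    cfg = replace(synth.ScenarioConfig(), n_genes=n_genes,
                  n_modules=n_modules, within_cor=within_cor,
                  n_snps=1000)
    ds = synth.simulate_scenario(cfg, seed=seed)
    filtered, flog = coexnet.filter_probes(ds.expression, top_var=n_genes,
                                           top_conn=n_genes)
    net = coexnet.build_network(filtered, beta=flog.beta)
    gene_of = dict(zip(filtered.probe_annotation["probe_id"],
                       filtered.probe_annotation["gene_symbol"]))
    truth_labels = [ds.truth.module_assignment[gene_of[p]]
                    for p in net.gene_ids]
    return float(adjusted_rand_score(truth_labels, list(net.labels)))


def eqtl_power(n_seeds: int = 20, seed0: int = 0, n_snps: int = 1000,
               alpha: float = 0.05) -> dict:
    """Fraction of seeds in which every planted cis-eQTL gene tested inside
    a locus around it reaches the Bonferroni threshold, plus the per-gene
    detection fraction."""
    detected, tested = 0, 0
    per_seed = []
    for i in range(n_seeds):
        cfg = replace(synth.ScenarioConfig(), n_snps=n_snps, n_eqtl=5)
        ds = synth.simulate_scenario(cfg, seed=seed0 + i)
        K = mm.ibs_kinship(ds.panel, mm.snp_filters(ds.panel).mask)
        hits = 0
        for gene, snp, effect in ds.truth.eqtl_truth:
            row = ds.genes.data[ds.genes.data["gene_id"] == gene].iloc[0]
            center = (int(row.txStart) + int(row.txEnd)) // 2
            locus = loci_mod.Locus(
                trait="expr", chrom=str(row.chrom), peak_snp=snp,
                peak_pos=center, peak_neglog10p=np.nan, peak_maf=np.nan,
                ci_start=max(1, center - loci_mod.DEFAULT_HALF_WIDTH_BP),
                ci_end=center + loci_mod.DEFAULT_HALF_WIDTH_BP)
            recs = loci_mod.local_eqtl_scan(ds.expression, ds.panel, locus,
                                            K, ds.genes, alpha=alpha)
            mine = [r for r in recs if r.gene_id == gene]
            if mine:
                tested += 1
                hits += int(mine[0].significant)
                detected += int(mine[0].significant)
        per_seed.append(hits)
    return {"n_tested": tested, "n_detected": detected,
            "fraction": detected / tested if tested else float("nan"),
            "per_seed": per_seed}
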