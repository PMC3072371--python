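"""Synthetic inbred-panel generator with known ground truth.

Emulates a hybrid diversity panel of ~100 strains: classical strains drawn
from shared ancestral haplotype blocks (which induces kinship structure and
LD, the confounding a mixed model must correct) plus recombinant-inbred
strains built as Poisson-breakpoint mosaics of two designated founders.
On top of the genotypes it plants:

* a heritable quantitative trait with a causal coding SNP explaining a
  configured fraction of strain-mean variance and an infinitesimal
  polygenic term (small i.i.d. effects on every common SNP);
* a modular expression matrix (one latent eigengene per module) with
  cis-eQTL genes whose expression tracks a nearby SNP;
* gene annotations, a non-synonymous SNP table in which the causal SNP is
  a damaging coding variant inside its gene, and a gene-set collection
  with one set concentrated in a single expression module.

Every generator is a pure function of (config, seed), so downstream
recovery experiments can score themselves against the recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneAnnotation, GenotypePanel, GeneSetCollection, NsSnpTable, PhenotypeTable

BASELINE_TRAIT = 10.0       # arbitrary positive offset keeping trait values > 0
BASELINE_EXPR = 8.0         # log2-intensity-like offset
SNP_SPACING_BP = 20_000     # mean inter-SNP distance


@dataclass
class ScenarioConfig:
    """Default desk-scale scenario: 100 strains (30 classical + 70 RI),
    5,000 SNPs on 5 chromosomes, 9 replicates per strain, 600 genes in
    5 expression modules."""

    n_classical: int = 30
    n_ri: int = 70
    n_snps: int = 5000
    n_chrom: int = 5
    n_ancestral: int = 12
    block_snps: int = 10
    n_groups: int = 6
    structure_strength: float = 0.6
    mean_crossovers: float = 8.0
    reps_per_strain: int = 9
    h2: float = 0.7
    causal_frac: float = 0.15
    trait: str = "bmd"
    n_genes: int = 600
    n_modules: int = 5
    within_cor: float = 0.7
    n_eqtl: int = 30
    eqtl_effect_sd: float = 1.5
    cis_window_bp: int = 1_000_000
    planted_set_size: int = 40
    planted_concentration: float = 0.75
    n_decoy_sets: int = 20


@dataclass
class PanelTruth:
    """Ground truth recorded alongside the synthetic data."""

    founder_ids: list
    ri_breakpoints: dict                       # ri strain -> {chrom: [(pos, founder), ...]}
    causal_snp_id: Optional[str] = None
    causal_gene: Optional[str] = None
    causal_frac: float = 0.0
    h2: float = 0.0
    sigma_g2: float = 0.0                      # model-scale polygenic variance (of sigma_g2 * K)
    sigma_e2: float = 0.0                      # replicate noise variance
    strain_genetic_values: Optional[dict] = None
    module_assignment: dict = field(default_factory=dict)   # gene -> module index
    eqtl_truth: list = field(default_factory=list)          # (gene, snp, effect)
    planted_set: list = field(default_factory=list)
    planted_module: int = 0
    gene_table: Optional[pd.DataFrame] = None  # gene_id, chrom, txStart, txEnd, strand, module

    def to_json_dict(self) -> dict:
        d = {
            "founder_ids": list(self.founder_ids),
            "causal_snp_id": self.causal_snp_id,
            "causal_gene": self.causal_gene,
            "causal_frac": self.causal_frac,
            "h2": self.h2,
            "sigma_g2": self.sigma_g2,
            "sigma_e2": self.sigma_e2,
            "module_assignment": self.module_assignment,
            "eqtl_truth": [list(t) for t in self.eqtl_truth],
            "planted_set": list(self.planted_set),
            "planted_module": self.planted_module,
        }
        return d


# ----------------------------------------------------------------- genotypes

def simulate_panel(n_classical: int, n_ri: int, n_snps: int, n_chrom: int,
                   seed: int, n_ancestral: int = 12, block_snps: int = 10,
                   n_groups: int = 6, structure_strength: float = 0.6,
                   mean_crossovers: float = 8.0) -> tuple[GenotypePanel, PanelTruth]:
    """Structured strain genotypes: ancestral-block classical strains plus
    recombinant-inbred mosaics of the first two classical strains."""
    if n_classical < 2:
        raise ValueError("need at least 2 classical strains (the RI founders)")
    if n_snps < n_chrom:
        raise ValueError("n_snps must be >= n_chrom")
    rng = np.random.default_rng(seed)

    per_chrom = [n_snps // n_chrom] * n_chrom
    for i in range(n_snps % n_chrom):
        per_chrom[i] += 1
    chroms, poss = [], []
    for c, m in enumerate(per_chrom, start=1):
        L = m * SNP_SPACING_BP
        p = np.sort(rng.choice(np.arange(1, L + 1), size=m, replace=False))
        chroms.extend([f"chr{c}"] * m)
        poss.extend(p.tolist())
    chroms = np.asarray(chroms, dtype=object)
    poss = np.asarray(poss, dtype=np.int64)

    # ancestral haplotypes, Bernoulli(1/2) alleles per SNP
    anc = rng.integers(0, 2, size=(n_ancestral, n_snps)).astype(float)

    # classical strains: per-block ancestral haplotype choice with a
    # group-preferred haplotype (structure_strength = preference weight)
    classical = np.empty((n_classical, n_snps))
    group_of = np.arange(n_classical) % n_groups
    snp_order = np.arange(n_snps)
    blocks = [snp_order[i:i + block_snps] for i in range(0, n_snps, block_snps)]
    # distinct preferred haplotypes per block keep groups (and hence the
    # two RI founders) well diverged
    pref = np.stack([rng.choice(n_ancestral, size=n_groups, replace=False)
                     for _ in blocks], axis=1)
    for s in range(n_classical):
        for b, idx in enumerate(blocks):
            if rng.random() < structure_strength:
                h = pref[group_of[s], b]
            else:
                h = rng.integers(0, n_ancestral)
            classical[s, idx] = anc[h, idx]

    strain_ids = [f"C{s:03d}" for s in range(n_classical)] + \
                 [f"RI{s:03d}" for s in range(n_ri)]
    founder_ids = [strain_ids[0], strain_ids[1]]
    fA, fB = classical[0], classical[1]

    ri = np.empty((n_ri, n_snps))
    breakpoints: dict = {}
    chrom_labels = [f"chr{c}" for c in range(1, n_chrom + 1)]
    for s in range(n_ri):
        bp_rec: dict = {}
        geno = np.empty(n_snps)
        for c in chrom_labels:
            on_c = chroms == c
            cpos = poss[on_c]
            L = int(cpos.max()) if cpos.size else 1
            k = rng.poisson(mean_crossovers)
            cuts = np.sort(rng.integers(1, L + 1, size=k))
            current = int(rng.integers(0, 2))
            segs = []
            start = 1
            for cut in list(cuts) + [L + 1]:
                segs.append((start, cut - 1, current))
                start = cut
                current = 1 - current
            src = np.empty(on_c.sum(), dtype=int)
            for lo, hi, f in segs:
                inseg = (cpos >= lo) & (cpos <= hi)
                src[inseg] = f
            geno[on_c] = np.where(src == 0, fA[on_c], fB[on_c])
            bp_rec[c] = [(int(lo), founder_ids[f]) for lo, hi, f in segs]
        ri[s] = geno
        breakpoints[strain_ids[n_classical + s]] = bp_rec

    calls = np.vstack([classical, ri]) if n_ri else classical
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    panel = GenotypePanel(
        snp_ids=np.asarray([f"snp{j:06d}" for j in range(n_snps)], dtype=object),
        chrom=chroms, pos=poss,
        ref=bases[ref_idx].astype(object), alt=bases[alt_idx].astype(object),
        calls=calls,
        strain_ids=np.asarray(strain_ids, dtype=object),
    )

    truth = PanelTruth(founder_ids=founder_ids, ri_breakpoints=breakpoints)
    truth.causal_snp_id = _pick_causal_snp(panel, rng,
                                           founder_ids=founder_ids if n_ri else None)
    return panel, truth


def _pick_causal_snp(panel: GenotypePanel, rng: np.random.Generator,
                     founder_ids: Optional[list] = None) -> str:
    """A mid-chromosome common SNP (MAF in [0.15, 0.45]) so the locus
    confidence interval is not clipped and the variant survives filters.

    The SNP must also segregate between the two RI founders: a variant on
    which the founders agree is monomorphic across the whole RI subpanel,
    leaving its variance confined to the small, heavily structured
    classical subset — an artifact of the two-founder mosaic design that a
    panel-wide common variant would not show.
    """
    maf = panel.maf()
    lengths = panel.chrom_lengths()
    margin = 2_000_000
    ok = (maf >= 0.15) & (maf <= 0.45)
    if founder_ids:
        fa = panel.calls[panel.strain_index(founder_ids[0])]
        fb = panel.calls[panel.strain_index(founder_ids[1])]
        ok &= fa != fb
    for j in range(panel.n_snps):
        L = lengths[str(panel.chrom[j])]
        if not (margin < panel.pos[j] < L - margin):
            ok[j] = False
    candidates = np.flatnonzero(ok)
    if candidates.size == 0:
        candidates = np.flatnonzero(maf >= 0.05)
    return str(panel.snp_ids[rng.choice(candidates)])


# ---------------------------------------------------------------- phenotypes

def simulate_phenotypes(panel: GenotypePanel, truth: PanelTruth,
                        reps_per_strain: int, h2: float, causal_frac: float,
                        seed: int, trait: str = "bmd") -> PhenotypeTable:
    """Replicate phenotypes with a planted causal SNP and polygenic term.

    Variance budget on the strain-mean scale (total 1): causal_frac from
    the causal SNP, h2 - causal_frac polygenic with covariance ~ K, and
    1 - h2 from averaged replicate noise, so h2 is the heritability of
    strain means.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must be in [0, 1]")
    if causal_frac > h2:
        raise ValueError(
            "causal_frac + polygenic fraction exceeds the genetic budget "
            f"(causal_frac={causal_frac} > h2={h2})"
        )
    rng = np.random.default_rng(seed + 1)
    s = panel.n_strains
    g = np.zeros(s)
    xs = None
    if causal_frac > 0:
        j = panel.snp_index(truth.causal_snp_id)
        x = panel.calls[:, j]
        if np.isnan(x).any():
            raise ValueError("causal SNP has missing calls")
        xs = (x - x.mean()) / x.std()
        g += np.sqrt(causal_frac) * xs
    poly_frac = h2 - causal_frac
    sigma_g2_model = 0.0
    if poly_frac > 0:
        from .mixedmodel import ibs_kinship, snp_filters
        # infinitesimal polygenic background: small i.i.d. effects on every
        # common SNP except the causal one, so no single background marker
        # carries more than a sliver of the genetic variance
        mask = snp_filters(panel).mask
        if truth.causal_snp_id is not None:
            mask = mask.copy()
            mask[panel.snp_index(truth.causal_snp_id)] = False
        Xp = np.nan_to_num(panel.calls[:, mask])
        Xp = Xp - Xp.mean(axis=0)
        u = Xp @ rng.standard_normal(Xp.shape[1])
        if xs is not None:
            # remove the projection onto the causal direction so the planted
            # SNP explains exactly causal_frac of strain variance
            u = u - xs * float(xs @ u) / float(xs @ xs)
        u = (u - u.mean()) / u.std() * np.sqrt(poly_frac)
        g += u
        # K-scale equivalent of the planted polygenic variance, for
        # comparison with REML estimates: var(Cu) ~ sigma_g2 tr(CKC)/(s-1)
        K = ibs_kinship(panel).values
        C = np.eye(s) - 1.0 / s
        c = float(np.trace(C @ K @ C)) / (s - 1)
        sigma_g2_model = poly_frac / c

    sigma_e2 = reps_per_strain * (1.0 - h2)
    rows = []
    for i, strain in enumerate(panel.strain_ids):
        eps = rng.standard_normal(reps_per_strain) * np.sqrt(sigma_e2)
        for r in range(reps_per_strain):
            rows.append((f"{strain}_r{r}", strain, trait,
                         BASELINE_TRAIT + g[i] + eps[r]))
    truth.causal_frac = causal_frac
    truth.h2 = h2
    truth.sigma_g2 = float(sigma_g2_model)   # K-scale polygenic variance
    truth.sigma_e2 = float(sigma_e2)
    truth.strain_genetic_values = {str(sid): float(v)
                                   for sid, v in zip(panel.strain_ids, g)}
    return PhenotypeTable(pd.DataFrame(
        rows, columns=["animal_id", "strain_id", "trait", "value"]))


# ---------------------------------------------------------------- expression

def _tile_genes(panel: GenotypePanel, truth: PanelTruth, n_genes: int,
                n_modules: int) -> pd.DataFrame:
    """Evenly tile genes along chromosomes; the gene nearest the causal SNP
    is re-centred on it so the causal variant is a coding SNP."""
    lengths = panel.chrom_lengths()
    chrom_labels = sorted(lengths, key=lambda c: int(c.replace("chr", "")))
    per = [n_genes // len(chrom_labels)] * len(chrom_labels)
    for i in range(n_genes % len(chrom_labels)):
        per[i] += 1
    rows = []
    gid = 0
    for c, m in zip(chrom_labels, per):
        spacing = lengths[c] // (m + 1)
        glen = max(5_000, int(spacing * 0.5))
        for i in range(m):
            start = (i + 1) * spacing - glen // 2
            rows.append((f"gene{gid:04d}", c, max(1, start), max(1, start) + glen - 1, "+"))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "txStart", "txEnd", "strand"])

    j = panel.snp_index(truth.causal_snp_id)
    c, p = str(panel.chrom[j]), int(panel.pos[j])
    on_c = genes["chrom"] == c
    centers = (genes.loc[on_c, "txStart"] + genes.loc[on_c, "txEnd"]) // 2
    nearest = (centers - p).abs().idxmin()
    half = int(genes.loc[nearest, "txEnd"] - genes.loc[nearest, "txStart"]) // 2
    genes.loc[nearest, "txStart"] = max(1, p - half)
    genes.loc[nearest, "txEnd"] = p + half
    truth.causal_gene = str(genes.loc[nearest, "gene_id"])

    module = np.arange(n_genes) * n_modules // n_genes  # contiguous equal blocks
    genes["module"] = module
    return genes


def simulate_expression(panel: GenotypePanel, truth: PanelTruth,
                        n_genes: int, n_modules: int, within_cor: float,
                        eqtl_effects: Optional[dict] = None,
                        seed: int = 0) -> ExpressionMatrix:
    """Modular strain-level expression (one array per strain) with planted
    cis-eQTL genes.

    Each module has one latent eigengene per strain; gene value =
    sqrt(within_cor) * eigengene + sqrt(1 - within_cor) * noise, so the
    expected within-module correlation is within_cor. eQTL genes add
    effect * standardized genotype at a SNP inside the gene's cis window.
    """
    if n_modules > n_genes:
        raise ValueError("n_modules cannot exceed n_genes")
    opts = {"n_eqtl": 30, "effect_sd": 1.5, "cis_window_bp": 1_000_000}
    if eqtl_effects:
        opts.update(eqtl_effects)
    rng = np.random.default_rng(seed + 2)
    genes = _tile_genes(panel, truth, n_genes, n_modules)
    truth.gene_table = genes
    truth.module_assignment = dict(zip(genes["gene_id"], genes["module"].astype(int)))

    s = panel.n_strains
    E = rng.standard_normal((n_modules, s))
    load = np.sqrt(within_cor)
    noise_sd = np.sqrt(1.0 - within_cor)
    X = np.empty((n_genes, s))
    for i, mod in enumerate(genes["module"]):
        X[i] = load * E[mod] + noise_sd * rng.standard_normal(s)

    # plant cis-eQTLs on genes other than the causal-trait gene
    eligible = [i for i in range(n_genes)
                if genes.loc[i, "gene_id"] != truth.causal_gene]
    chosen = rng.choice(eligible, size=min(opts["n_eqtl"], len(eligible)),
                        replace=False)
    truth.eqtl_truth = []
    maf = panel.maf()
    for i in sorted(chosen):
        row = genes.loc[i]
        center = (int(row.txStart) + int(row.txEnd)) // 2
        on_c = (panel.chrom == row.chrom) & \
               (np.abs(panel.pos - center) <= opts["cis_window_bp"]) & \
               (maf >= 0.05)
        cand = np.flatnonzero(on_c)
        if cand.size == 0:
            continue
        j = cand[np.argmin(np.abs(panel.pos[cand] - center))]
        gsnp = panel.calls[:, j]
        gs = (gsnp - np.nanmean(gsnp)) / np.nanstd(gsnp)
        effect = opts["effect_sd"] * noise_sd if noise_sd > 0 else opts["effect_sd"]
        X[i] += effect * np.nan_to_num(gs)
        truth.eqtl_truth.append((str(row.gene_id), str(panel.snp_ids[j]),
                                 float(effect)))

    probe_rows = []
    snp_pos_by_chrom = {c: panel.pos[panel.chrom == c] for c in set(panel.chrom)}
    for _, row in genes.iterrows():
        start = int(row.txStart)
        # 50 bp probe footprint placed to avoid panel SNPs (hybridization artifacts)
        pos_on_c = snp_pos_by_chrom[row.chrom]
        for cand_start in range(start, int(row.txEnd) - 49, 50):
            inside = (pos_on_c >= cand_start) & (pos_on_c <= cand_start + 49)
            if not inside.any():
                start = cand_start
                break
        probe_rows.append((f"probe_{row.gene_id}", row.gene_id, row.chrom,
                           start, start + 49))
    ann = pd.DataFrame(probe_rows, columns=["probe_id", "gene_symbol",
                                            "chrom", "start", "end"])
    values = pd.DataFrame(BASELINE_EXPR + X, index=ann["probe_id"].tolist(),
                          columns=list(panel.strain_ids))
    return ExpressionMatrix(
        values=values,
        sample_strains=pd.Series(list(panel.strain_ids),
                                 index=list(panel.strain_ids)),
        probe_annotation=ann,
    )


# --------------------------------------------------------------- annotations

def simulate_annotations(panel: GenotypePanel, truth: PanelTruth,
                         planted_set_size: int = 40,
                         planted_concentration: float = 0.75,
                         n_decoy_sets: int = 20,
                         n_benign_decoys: int = 20,
                         seed: int = 0) -> tuple[GeneAnnotation, NsSnpTable, GeneSetCollection]:
    """Gene intervals, a non-synonymous SNP table (the causal SNP is a
    damaging variant inside its gene; decoys are benign), and gene sets
    with one set concentrated in the planted module."""
    if truth.gene_table is None:
        raise ValueError("run simulate_expression first (gene tiling lives there)")
    rng = np.random.default_rng(seed + 3)
    genes = truth.gene_table
    ann = GeneAnnotation(genes[["gene_id", "chrom", "txStart", "txEnd", "strand"]].copy())

    aa = list("ACDEFGHIKLMNPQRSTVWY")
    ns_rows = []
    j = panel.snp_index(truth.causal_snp_id)
    ns_rows.append((truth.causal_snp_id, str(panel.chrom[j]), int(panel.pos[j]),
                    f"{panel.ref[j]}/{panel.alt[j]}", truth.causal_gene,
                    "Probably Damaging",
                    f"{rng.choice(aa)}{rng.integers(50, 900)}{rng.choice(aa)}"))
    # benign decoys: SNPs falling inside other gene bodies
    other = genes[genes["gene_id"] != truth.causal_gene]
    candidates = []
    for _, row in other.iterrows():
        inside = np.flatnonzero((panel.chrom == row.chrom) &
                                (panel.pos >= row.txStart) &
                                (panel.pos <= row.txEnd))
        for k in inside:
            candidates.append((k, row.gene_id))
    rng.shuffle(candidates)
    for k, gid in candidates[:n_benign_decoys]:
        ns_rows.append((str(panel.snp_ids[k]), str(panel.chrom[k]),
                        int(panel.pos[k]), f"{panel.ref[k]}/{panel.alt[k]}",
                        gid, "Benign",
                        f"{rng.choice(aa)}{rng.integers(50, 900)}{rng.choice(aa)}"))
    ns = NsSnpTable(pd.DataFrame(ns_rows, columns=[
        "snp_id", "chrom", "pos", "alleles", "gene_id", "effect_class",
        "aa_change"]))

    all_genes = genes["gene_id"].tolist()
    module_genes = [g for g, m in truth.module_assignment.items()
                    if m == truth.planted_module]
    n_in = int(round(planted_set_size * planted_concentration))
    n_out = planted_set_size - n_in
    outside = [g for g in all_genes if g not in set(module_genes)]
    planted = (list(rng.choice(module_genes, size=n_in, replace=False)) +
               list(rng.choice(outside, size=n_out, replace=False)))
    truth.planted_set = sorted(planted)
    sets = {"myeloid cell differentiation": set(planted)}
    descriptions = {"myeloid cell differentiation":
                    "planted set concentrated in one module"}
    for d in range(n_decoy_sets):
        size = int(rng.integers(15, 60))
        name = f"decoy_set_{d:02d}"
        sets[name] = set(rng.choice(all_genes, size=size, replace=False))
        descriptions[name] = "random decoy set"
    return ann, ns, GeneSetCollection(sets=sets, descriptions=descriptions,
                                      universe=set(all_genes))


# ----------------------------------------------------------------- scenario

@dataclass
class SyntheticDataset:
    config: ScenarioConfig
    seed: int
    panel: GenotypePanel
    truth: PanelTruth
    phenotypes: PhenotypeTable
    expression: ExpressionMatrix
    genes: GeneAnnotation
    ns_snps: NsSnpTable
    gene_sets: GeneSetCollection


def simulate_scenario(config: Optional[ScenarioConfig] = None,
                      seed: int = 0) -> SyntheticDataset:
    """Run every generator with one seed; the one-stop default scenario."""
    cfg = config or ScenarioConfig()
    panel, truth = simulate_panel(
        cfg.n_classical, cfg.n_ri, cfg.n_snps, cfg.n_chrom, seed,
        n_ancestral=cfg.n_ancestral, block_snps=cfg.block_snps,
        n_groups=cfg.n_groups, structure_strength=cfg.structure_strength,
        mean_crossovers=cfg.mean_crossovers,
    )
    pheno = simulate_phenotypes(panel, truth, cfg.reps_per_strain, cfg.h2,
                                cfg.causal_frac, seed, trait=cfg.trait)
    expr = simulate_expression(
        panel, truth, cfg.n_genes, cfg.n_modules, cfg.within_cor,
        eqtl_effects={"n_eqtl": cfg.n_eqtl, "effect_sd": cfg.eqtl_effect_sd,
                      "cis_window_bp": cfg.cis_window_bp},
        seed=seed,
    )
    genes, ns, sets = simulate_annotations(
        panel, truth, planted_set_size=cfg.planted_set_size,
        planted_concentration=cfg.planted_concentration,
        n_decoy_sets=cfg.n_decoy_sets, seed=seed,
    )
    return SyntheticDataset(config=cfg, seed=seed, panel=panel, truth=truth,
                            phenotypes=pheno, expression=expr, genes=genes,
                            ns_snps=ns, gene_sets=sets)
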