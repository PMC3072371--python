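"""Readers and writers for the on-disk formats used by the pipeline.

Genotypes travel as a simple strain x SNP TSV (inbred panels are
haploid-equivalent); a VCF convenience reader keeps only homozygous calls.
BED input (0-based half-open) is converted to the package's 1-based
inclusive convention at this boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import GenotypePanel, GeneAnnotation, GeneSetCollection, NsSnpTable, PhenotypeTable, ExpressionMatrix

log = logging.getLogger("strainmap.io")

MISSING_TOKEN = "NA"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- genotypes

def read_genotypes(path, dialect: str = "tsv") -> GenotypePanel:
    """Load a genotype panel from TSV (default) or VCF.

    TSV layout: header ``snp_id chrom pos ref alt <strain...>``, then one
    row per SNP with calls 0/1/NA. VCF: homozygous genotypes only;
    heterozygous calls become missing with a logged warning count.
    """
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype dialect: {dialect}")


def _read_genotypes_tsv(path) -> GenotypePanel:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["snp_id", "chrom", "pos", "ref", "alt"]:
            raise ParseError(
                f"{path}:1: expected header starting with "
                "snp_id/chrom/pos/ref/alt"
            )
        strains = header[5:]
        snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 + len(strains):
                raise ParseError(
                    f"{path}:{lineno}: expected {5 + len(strains)} fields, "
                    f"got {len(parts)}"
                )
            sid = parts[0]
            if sid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate snp_id {sid!r}")
            seen.add(sid)
            try:
                pos = int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad position {parts[2]!r}")
            calls = []
            for tok in parts[5:]:
                if tok == MISSING_TOKEN:
                    calls.append(np.nan)
                elif tok in ("0", "1"):
                    calls.append(float(tok))
                else:
                    raise ParseError(
                        f"{path}:{lineno}: invalid call {tok!r} "
                        "(expected 0, 1 or NA)"
                    )
            snp_ids.append(sid)
            chroms.append(parts[1])
            poss.append(pos)
            refs.append(parts[3])
            alts.append(parts[4])
            rows.append(calls)
    calls = np.asarray(rows, dtype=float).T if rows else np.empty((len(strains), 0))
    return GenotypePanel(
        snp_ids=np.asarray(snp_ids, dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        calls=calls,
        strain_ids=np.asarray(strains, dtype=object),
    )


def _read_genotypes_vcf(path) -> GenotypePanel:
    """VCF reader (via cyvcf2): biallelic sites, homozygous calls only."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:
        raise ImportError(
            "VCF support requires cyvcf2 (pip install strainmap[vcf])"
        ) from exc
    path = Path(path)
    vcf = VCF(str(path), gts012=True)
    strains = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_het = 0
    seen = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"{path}: multi-allelic site at {rec.CHROM}:{rec.POS}")
        sid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if sid in seen:
            raise ParseError(f"{path}: duplicate snp_id {sid!r}")
        seen.add(sid)
        calls = []
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        for gt in rec.gt_types:
            if gt == 0:
                calls.append(0.0)
            elif gt == 2:
                calls.append(1.0)
            else:
                if gt == 1:
                    n_het += 1
                calls.append(np.nan)
        snp_ids.append(sid)
        chroms.append(rec.CHROM)
        poss.append(int(rec.POS))
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(calls)
    if n_het:
        log.warning("VCF %s: %d heterozygous genotype(s) set to missing", path, n_het)
    calls = np.asarray(rows, dtype=float).T if rows else np.empty((len(strains), 0))
    return GenotypePanel(
        snp_ids=np.asarray(snp_ids, dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        calls=calls,
        strain_ids=np.asarray(strains, dtype=object),
    )


def write_genotypes(panel: GenotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["snp_id", "chrom", "pos", "ref", "alt", *panel.strain_ids]) + "\n")
        for j in range(panel.n_snps):
            col = panel.calls[:, j]
            toks = [MISSING_TOKEN if np.isnan(v) else str(int(v)) for v in col]
            fh.write(
                "\t".join(
                    [
                        str(panel.snp_ids[j]),
                        str(panel.chrom[j]),
                        str(panel.pos[j]),
                        str(panel.ref[j]),
                        str(panel.alt[j]),
                        *toks,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------- intervals

def read_bed(path) -> GeneAnnotation:
    """BED3+ genes -> 1-based inclusive annotation.

    txStart = bed_start + 1, txEnd = bed_end; overlapping genes are kept
    unmerged.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line with <3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ParseError(
                    f"{path}:{lineno}: BED end {end} <= start {start}"
                )
            gene_id = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((gene_id, chrom, start + 1, end, strand))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "txStart", "txEnd", "strand"])
    )


def write_bed(ann: GeneAnnotation, path) -> None:
    """Inverse of read_bed: 1-based inclusive -> 0-based half-open."""
    with open(path, "w") as fh:
        for row in ann.data.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.txStart - 1}\t{row.txEnd}\t{row.gene_id}\t0\t{row.strand}\n"
            )


# ---------------------------------------------------------------- gene sets

def read_gmt(path, universe: Optional[set] = None) -> GeneSetCollection:
    """Standard GMT: name <tab> description <tab> members...

    Duplicate members in a line are counted once. If a universe is supplied,
    members outside it are dropped with a logged count; the default universe
    is the union of all sets.
    """
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT set with zero members"
                )
            name, desc = parts[0], parts[1]
            members = {m for m in parts[2:] if m}
            if universe is not None:
                kept = members & universe
                n_dropped += len(members) - len(kept)
                members = kept
            if not members:
                raise ParseError(f"{path}:{lineno}: GMT set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    if n_dropped:
        log.warning("GMT %s: dropped %d member(s) outside the universe", path, n_dropped)
    return GeneSetCollection(sets=sets, descriptions=descriptions, universe=universe)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------- tables

def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, index=False)


def read_expression(values_path, annotation_path, sample_strain_path=None,
                    detection_path=None) -> ExpressionMatrix:
    """Expression TSV (probes x samples) + probe annotation TSV.

    Sample -> strain mapping defaults to identity (one array per strain,
    sample ids are strain ids) unless a two-column TSV is given.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t")
    if sample_strain_path is not None:
        m = pd.read_csv(sample_strain_path, sep="\t")
        sample_strains = pd.Series(m["strain_id"].values, index=m["sample_id"].values)
    else:
        sample_strains = pd.Series(values.columns, index=values.columns)
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, sample_strains=sample_strains,
                            probe_annotation=ann, detection=detection)


def write_expression(expr: ExpressionMatrix, values_path, annotation_path) -> None:
    expr.values.to_csv(values_path, sep="\t")
    expr.probe_annotation.to_csv(annotation_path, sep="\t", index=False)


def read_ns_snps(path) -> NsSnpTable:
    return NsSnpTable(pd.read_csv(path, sep="\t"))


def write_ns_snps(table: NsSnpTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
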