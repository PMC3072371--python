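"""Core in-memory containers shared across the pipeline.

All genomic coordinates are 1-based inclusive throughout the package;
0-based half-open conventions (BED) are converted at the I/O boundary.
Inbred strains are homozygous, so genotype calls are coded 0 (reference
allele) / 1 (alternate allele), with NaN marking missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class GenotypePanel:
    """Strain x SNP homozygous genotype calls for an inbred panel.

    ``calls`` is a float matrix of shape (n_strains, n_snps) with values in
    {0.0, 1.0, NaN}; SNPs are sorted by (chrom, pos).
    """

    snp_ids: np.ndarray          # (m,) str
    chrom: np.ndarray            # (m,) str
    pos: np.ndarray              # (m,) int, 1-based bp
    ref: np.ndarray              # (m,) str
    alt: np.ndarray              # (m,) str
    calls: np.ndarray            # (s, m) float in {0, 1, nan}
    strain_ids: np.ndarray       # (s,) str

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=float)
        self.strain_ids = np.asarray(self.strain_ids, dtype=object)
        if (self.pos <= 0).any():
            raise ValueError("SNP positions must be strictly positive")
        ok = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not ok.all():
            raise ValueError("genotype calls must be 0, 1 or missing")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_id in panel")
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self._reorder(order)

    def _reorder(self, order: np.ndarray) -> None:
        for name in ("snp_ids", "chrom", "pos", "ref", "alt"):
            setattr(self, name, getattr(self, name)[order])
        self.calls = self.calls[:, order]

    @property
    def n_strains(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing strain calls.

        All-missing SNPs get MAF NaN.
        """
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.calls, axis=0)
        return np.minimum(freq, 1.0 - freq)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown snp id: {snp_id}")
        return int(idx[0])

    def strain_index(self, strain_id: str) -> int:
        idx = np.flatnonzero(self.strain_ids == strain_id)
        if idx.size == 0:
            raise KeyError(f"unknown strain id: {strain_id}")
        return int(idx[0])

    def chrom_lengths(self) -> dict[str, int]:
        """Max observed SNP position per chromosome (proxy for length)."""
        out: dict[str, int] = {}
        for c in np.unique(self.chrom.astype(str)):
            out[c] = int(self.pos[self.chrom == c].max())
        return out


@dataclass
class PhenotypeTable:
    """Replicate-level phenotype records in long format.

    ``data`` columns: animal_id, strain_id, trait, value and optional
    covariates (age, weight, sex, genotype_group).
    """

    data: pd.DataFrame

    REQUIRED = ("animal_id", "strain_id", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if not np.isfinite(self.data["value"].to_numpy(float)).all():
            raise ValueError("phenotype values must be finite")

    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def trait_frame(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if len(sub) == 0:
            raise KeyError(f"trait not present: {trait}")
        return sub.copy()


@dataclass
class ExpressionMatrix:
    """Probe x sample normalized log-scale expression.

    ``samples`` maps each sample (array) to its strain; probe_annotation
    gives each probe's gene and genomic footprint (1-based inclusive).
    """

    values: pd.DataFrame                  # probes x samples
    sample_strains: pd.Series             # sample_id -> strain_id
    probe_annotation: pd.DataFrame        # probe_id, gene_symbol, chrom, start, end
    detection: Optional[pd.DataFrame] = None   # probe x sample detection P

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        ann_probes = set(self.probe_annotation["probe_id"])
        unannotated = set(self.values.index) - ann_probes
        if unannotated:
            raise ValueError(
                f"{len(unannotated)} probes lack annotation, e.g. "
                f"{sorted(unannotated)[:3]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_probes(self, probes) -> "ExpressionMatrix":
        probes = list(probes)
        det = self.detection.loc[probes] if self.detection is not None else None
        return ExpressionMatrix(
            values=self.values.loc[probes],
            sample_strains=self.sample_strains,
            probe_annotation=self.probe_annotation[
                self.probe_annotation["probe_id"].isin(probes)
            ].reset_index(drop=True),
            detection=det,
        )


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive, unique gene_id."""

    data: pd.DataFrame   # gene_id, chrom, txStart, txEnd, strand

    def __post_init__(self) -> None:
        d = self.data
        if len(d) and (d["txStart"] > d["txEnd"]).any():
            raise ValueError("gene with txStart > txEnd")
        if d["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in annotation")

    def __len__(self) -> int:
        return len(self.data)


EFFECT_CLASSES = ("Benign", "Possibly Damaging", "Probably Damaging", "Nonsense")
DAMAGING_CLASSES = ("Possibly Damaging", "Probably Damaging", "Nonsense")


@dataclass
class NsSnpTable:
    """Non-synonymous SNPs with functional-impact class labels."""

    data: pd.DataFrame   # snp_id, chrom, pos, alleles, gene_id, effect_class, aa_change

    def __post_init__(self) -> None:
        bad = set(self.data["effect_class"]) - set(EFFECT_CLASSES)
        if bad:
            raise ValueError(f"unknown effect classes: {sorted(bad)}")
        if len(self.data) and (self.data["pos"] <= 0).any():
            raise ValueError("NS SNP positions must be positive")

    def damaging(self) -> pd.DataFrame:
        return self.data[self.data["effect_class"].isin(DAMAGING_CLASSES)].copy()


@dataclass
class GeneSetCollection:
    """Named gene sets plus a background universe of gene ids."""

    sets: dict[str, set]                 # name -> member gene ids
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: Optional[set] = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if self.universe is None:
            self.universe = set().union(*self.sets.values()) if self.sets else set()

    def __len__(self) -> int:
        return len(self.sets)
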