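"""Shared per-gene data model: SNP records, summary tables, reference panels.

Coordinates are 1-based and intervals are closed, following the bim/VCF
convention. Summary tables keep their SNPs in an explicit order so that
z-score vectors, LD matrices and weight vectors can be aligned positionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SnpRecord",
    "GeneAnnotation",
    "EqtlSummaryTable",
    "GwasSummaryTable",
    "ReferencePanel",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SnpRecord:
    """A single biallelic variant.

    ``alt_allele`` is the counted (effect) allele: genotypes in a
    :class:`ReferencePanel` count copies of it, and z-scores in summary
    tables are signed with respect to it.  ``cm`` is the genetic-map
    position in centimorgans and may be absent before map interpolation.
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: Optional[float] = None
    cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"SNP {self.snp_id}: position must be positive, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError(f"SNP {self.snp_id}: alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.snp_id}: ref and alt alleles are identical")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"SNP {self.snp_id}: MAF {self.maf} outside [0, 0.5]")

    @property
    def is_biallelic_snv(self) -> bool:
        a, b = self.ref_allele.upper(), self.alt_allele.upper()
        return a in COMPLEMENT and b in COMPLEMENT

    @property
    def is_ambiguous(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) pairs."""
        a, b = self.ref_allele.upper(), self.alt_allele.upper()
        return a in COMPLEMENT and COMPLEMENT[a] == b


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.tss <= 0 or self.tes <= 0:
            raise ValueError(f"{self.gene_id}: TSS/TES must be positive")
        if self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: TSS ({self.tss}) > TES ({self.tes})")


def _check_unique_ids(records: Sequence[SnpRecord], context: str) -> None:
    seen = set()
    for rec in records:
        if rec.snp_id in seen:
            raise ValueError(f"{context}: duplicate SNP id {rec.snp_id!r}")
        seen.add(rec.snp_id)


@dataclass
class EqtlSummaryTable:
    """Per-gene cis-eQTL summary statistics.

    ``z`` holds the per-SNP association z-scores and ``n`` the per-SNP
    sample sizes (these vary across SNPs in meta-analysed resources and
    are deliberately never collapsed to the cohort maximum).
    """

    gene_id: str
    records: list[SnpRecord]
    z: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if not (len(self.records) == self.z.shape[0] == self.n.shape[0]):
            raise ValueError(
                f"{self.gene_id}: records/z/n lengths differ "
                f"({len(self.records)}/{self.z.shape[0]}/{self.n.shape[0]})"
            )
        if not np.all(np.isfinite(self.z)):
            raise ValueError(f"{self.gene_id}: non-finite z-scores")
        if np.any(self.n < 2):
            bad = self.records[int(np.argmax(self.n < 2))].snp_id
            raise ValueError(f"{self.gene_id}: per-SNP sample size < 2 (e.g. {bad})")
        _check_unique_ids(self.records, f"gene {self.gene_id}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, idx: Sequence[int]) -> "EqtlSummaryTable":
        idx = np.asarray(idx, dtype=int)
        return EqtlSummaryTable(
            gene_id=self.gene_id,
            records=[self.records[i] for i in idx],
            z=self.z[idx],
            n=self.n[idx],
        )


@dataclass
class GwasSummaryTable:
    """GWAS z-scores over a set of SNPs, sign-aligned to the counted allele."""

    records: list[SnpRecord]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if len(self.records) != self.z.shape[0]:
            raise ValueError("records/z length mismatch")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite GWAS z-scores")
        _check_unique_ids(self.records, "GWAS table")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, idx: Sequence[int]) -> "GwasSummaryTable":
        idx = np.asarray(idx, dtype=int)
        return GwasSummaryTable(records=[self.records[i] for i in idx], z=self.z[idx])


@dataclass
class ReferencePanel:
    """Genotype matrix (samples x SNPs) with per-SNP metadata.

    Genotypes count copies of each SNP's ``alt_allele`` and may be hard
    calls in {0, 1, 2} or dosages in [0, 2]; missing values are NaN.
    """

    sample_ids: list[str]
    genotypes: np.ndarray
    records: list[SnpRecord]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.float32)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x SNPs)")
        if self.genotypes.shape != (len(self.sample_ids), len(self.records)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.records)} SNPs"
            )
        _check_unique_ids(self.records, "reference panel")
        all_missing = np.all(np.isnan(self.genotypes), axis=0)
        if np.any(all_missing):
            bad = self.records[int(np.argmax(all_missing))].snp_id
            raise ValueError(f"SNP {bad} has 100% missing genotypes")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset_snps(self, idx: Sequence[int]) -> "ReferencePanel":
        idx = np.asarray(idx, dtype=int)
        return ReferencePanel(
            sample_ids=self.sample_ids,
            genotypes=self.genotypes[:, idx],
            records=[self.records[i] for i in idx],
        )

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (missing genotypes ignored)."""
        freq = np.nanmean(self.genotypes, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def imputed(self) -> np.ndarray:
        """Genotypes with missing values mean-imputed per SNP (float64)."""
        g = self.genotypes.astype(np.float64)
        if np.any(np.isnan(g)):
            col_mean = np.nanmean(g, axis=0)
            nan_r, nan_c = np.nonzero(np.isnan(g))
            g[nan_r, nan_c] = col_mean[nan_c]
        return g

    def standardized(self) -> np.ndarray:
        """Mean-imputed genotypes scaled to mean 0, variance 1 per SNP.

        Raises on monomorphic SNPs (zero variance), which must be filtered
        out before any LD or model computation.
        """
        g = self.imputed()
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        if np.any(sd == 0):
            bad = self.records[int(np.argmax(sd == 0))].snp_id
            raise ValueError(f"SNP {bad} is monomorphic in the panel")
        return (g - mu) / sd

    def with_cm(self, cm: np.ndarray) -> "ReferencePanel":
        """Return a copy with genetic positions attached to each record."""
        cm = np.asarray(cm, dtype=float)
        if cm.shape[0] != self.n_snps:
            raise ValueError("cM vector length does not match SNP count")
        recs = [replace(r, cm=float(c)) for r, c in zip(self.records, cm)]
        return ReferencePanel(self.sample_ids, self.genotypes, recs)
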