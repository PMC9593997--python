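"""Readers, writers, and harmonization for summary statistics and genotypes.

Supported external formats:

* eQTL / GWAS summaries: tab-delimited text with a header; column names are
  configurable with eQTLGen-style defaults.
* Reference panels: PLINK bed/bim/fam (primary) or VCF (secondary, via
  cyvcf2).
* Genetic maps: tab-delimited ``(position, rate, cM)`` per chromosome
  (1000 Genomes OMNI style) or plain ``(chrom, pos, cM)``.
* Gene annotations: 4-column tab-delimited ``(gene_id, chrom, tss, tes)``
  or GTF (gene features only).
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import (
    COMPLEMENT,
    EqtlSummaryTable,
    GeneAnnotation,
    GwasSummaryTable,
    ReferencePanel,
    SnpRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EQTL_COLUMNS",
    "GWAS_COLUMNS",
    "EmptyTableError",
    "FormatError",
    "load_eqtl_summary",
    "load_gwas_summary",
    "write_eqtl_summary",
    "write_gwas_summary",
    "read_plink",
    "write_plink",
    "read_vcf",
    "read_genetic_map",
    "load_gene_annotations",
    "restrict_to_cis_window",
    "filter_snps",
    "harmonize_alleles",
    "align_panel",
]

# eQTLGen cis-eQTL column dialect.  "alt" is the assessed (counted) allele.
EQTL_COLUMNS = {
    "snp_id": "SNP",
    "gene_id": "Gene",
    "chrom": "SNPChr",
    "pos": "SNPPos",
    "alt": "AssessedAllele",
    "ref": "OtherAllele",
    "z": "Zscore",
    "n": "NrSamples",
}

GWAS_COLUMNS = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "alt": "A1",
    "ref": "A2",
    "z": "Z",
}


class FormatError(ValueError):
    """A mandatory column or field is missing or malformed."""


class EmptyTableError(ValueError):
    """A query matched zero rows (distinct from a malformed file)."""


def _require_columns(df: pd.DataFrame, colmap: dict, path) -> None:
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def load_eqtl_summary(
    path: Union[str, Path],
    gene: GeneAnnotation,
    columns: Optional[dict] = None,
) -> EqtlSummaryTable:
    """Load the cis-eQTL summary rows for one gene from a tab-delimited file.

    Rows are returned in file order; per-SNP sample sizes are kept as
    printed.  Raises :class:`EmptyTableError` when the gene has no rows.
    """
    colmap = dict(EQTL_COLUMNS)
    colmap.update(columns or {})
    df = pd.read_csv(path, sep="\t", dtype={colmap["snp_id"]: str, colmap["chrom"]: str})
    _require_columns(df, colmap, path)
    sub = df[df[colmap["gene_id"]].astype(str) == gene.gene_id]
    if len(sub) == 0:
        raise EmptyTableError(f"{path}: no rows for gene {gene.gene_id}")
    records = [
        SnpRecord(
            snp_id=str(row[colmap["snp_id"]]),
            chrom=str(row[colmap["chrom"]]),
            pos=int(row[colmap["pos"]]),
            ref_allele=str(row[colmap["ref"]]).upper(),
            alt_allele=str(row[colmap["alt"]]).upper(),
        )
        for _, row in sub.iterrows()
    ]
    return EqtlSummaryTable(
        gene_id=gene.gene_id,
        records=records,
        z=sub[colmap["z"]].to_numpy(dtype=float),
        n=sub[colmap["n"]].to_numpy(dtype=float),
    )


def write_eqtl_summary(path: Union[str, Path], table: EqtlSummaryTable, columns: Optional[dict] = None) -> None:
    colmap = dict(EQTL_COLUMNS)
    colmap.update(columns or {})
    df = pd.DataFrame(
        {
            colmap["snp_id"]: table.snp_ids,
            colmap["gene_id"]: table.gene_id,
            colmap["chrom"]: [r.chrom for r in table.records],
            colmap["pos"]: [r.pos for r in table.records],
            colmap["alt"]: [r.alt_allele for r in table.records],
            colmap["ref"]: [r.ref_allele for r in table.records],
            colmap["z"]: table.z,
            colmap["n"]: table.n.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_gwas_summary(path: Union[str, Path], columns: Optional[dict] = None) -> GwasSummaryTable:
    colmap = dict(GWAS_COLUMNS)
    colmap.update(columns or {})
    df = pd.read_csv(path, sep="\t", dtype={colmap["snp_id"]: str, colmap["chrom"]: str})
    _require_columns(df, colmap, path)
    records = [
        SnpRecord(
            snp_id=str(row[colmap["snp_id"]]),
            chrom=str(row[colmap["chrom"]]),
            pos=int(row[colmap["pos"]]),
            ref_allele=str(row[colmap["ref"]]).upper(),
            alt_allele=str(row[colmap["alt"]]).upper(),
        )
        for _, row in df.iterrows()
    ]
    return GwasSummaryTable(records=records, z=df[colmap["z"]].to_numpy(dtype=float))


def write_gwas_summary(path: Union[str, Path], table: GwasSummaryTable, columns: Optional[dict] = None) -> None:
    colmap = dict(GWAS_COLUMNS)
    colmap.update(columns or {})
    df = pd.DataFrame(
        {
            colmap["snp_id"]: table.snp_ids,
            colmap["chrom"]: [r.chrom for r in table.records],
            colmap["pos"]: [r.pos for r in table.records],
            colmap["alt"]: [r.alt_allele for r in table.records],
            colmap["ref"]: [r.ref_allele for r in table.records],
            colmap["z"]: table.z,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major

# 2-bit codes per PLINK spec: 00=hom A1, 01=missing, 10=het, 11=hom A2.
# We count copies of A1 (bim column 5), so 00 -> 2, 10 -> 1, 11 -> 0.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0], dtype=np.float32)

_BYTE_LUT = np.empty((256, 4), dtype=np.float32)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


def read_plink(prefix: Union[str, Path]) -> ReferencePanel:
    """Read a PLINK 1 binary fileset (``prefix`` + .bed/.bim/.fam).

    Genotypes count the bim A1 allele, which becomes ``alt_allele``.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * p:
        raise FormatError(f"{prefix}.bed: size does not match {n} samples x {p} SNPs")
    geno = _BYTE_LUT[body.reshape(p, bytes_per_snp)].reshape(p, -1)[:, :n].T
    records = [
        SnpRecord(
            snp_id=row.snp_id,
            chrom=row.chrom,
            pos=int(row.pos),
            ref_allele=str(row.a2).upper(),
            alt_allele=str(row.a1).upper(),
            cm=float(row.cm) if row.cm else None,
        )
        for row in bim.itertuples()
    ]
    return ReferencePanel(sample_ids=list(fam["iid"]), genotypes=geno, records=records)


def write_plink(prefix: Union[str, Path], panel: ReferencePanel) -> None:
    """Write a panel as PLINK bed/bim/fam (hard calls; dosages are rounded)."""
    prefix = Path(prefix)
    n, p = panel.n_samples, panel.n_snps
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in panel.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for r in panel.records:
            cm = r.cm if r.cm is not None else 0.0
            fh.write(f"{r.chrom}\t{r.snp_id}\t{cm}\t{r.pos}\t{r.alt_allele}\t{r.ref_allele}\n")
    g = np.rint(panel.genotypes)
    codes = np.full((p, n), 1, dtype=np.uint8)  # default: missing (01)
    gt = g.T
    codes[gt == 2] = 0
    codes[gt == 1] = 2
    codes[gt == 0] = 3
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((p, pad), dtype=np.uint8) + 3], axis=1)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes.reshape(p, -1, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: Union[str, Path]) -> ReferencePanel:
    """Read biallelic SNVs from a VCF into a panel (counts the ALT allele)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # multi-allelic records are dropped
        records.append(
            SnpRecord(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref_allele=var.REF.upper(),
                alt_allele=var.ALT[0].upper(),
            )
        )
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(np.float32)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        cols.append(dose)
    geno = np.stack(cols, axis=1) if cols else np.empty((len(sample_ids), 0), np.float32)
    return ReferencePanel(sample_ids=sample_ids, genotypes=geno, records=records)


# ---------------------------------------------------------------------------
# Genetic maps and annotations
# ---------------------------------------------------------------------------


def read_genetic_map(path: Union[str, Path]) -> pd.DataFrame:
    """Read a genetic map as a DataFrame with columns ``pos`` (bp) and ``cm``.

    Accepts the 1000G-OMNI per-chromosome layout (``position rate cM`` with a
    header) or a headerless 3-column ``chrom pos cm`` table.
    """
    head = pd.read_csv(path, sep=r"\s+", nrows=1, header=None)
    first = str(head.iloc[0, 0])
    if not first.replace(".", "", 1).lstrip("-").isdigit():
        df = pd.read_csv(path, sep=r"\s+")
        pos_col = df.columns[0]
        cm_col = df.columns[-1]
        out = pd.DataFrame({"pos": df[pos_col].astype(int), "cm": df[cm_col].astype(float)})
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None)
        if df.shape[1] < 3:
            raise FormatError(f"{path}: genetic map needs >= 3 columns")
        out = pd.DataFrame({"pos": df.iloc[:, 1].astype(int), "cm": df.iloc[:, 2].astype(float)})
    if len(out) == 0:
        raise FormatError(f"{path}: empty genetic map")
    return out.sort_values("pos").reset_index(drop=True)


def load_gene_annotations(path: Union[str, Path]) -> list[GeneAnnotation]:
    """Load gene annotations from 4-column TSV or GTF."""
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        genes = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.strip().split(" ", 1)
                    for kv in parts[8].rstrip(";").split(";")
                    if " " in kv.strip()
                )
                gid = attrs.get("gene_id", "").strip('"')
                genes.append(GeneAnnotation(gid, parts[0], int(parts[3]), int(parts[4])))
        return genes
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "chrom", "tss", "tes"],
        dtype={"gene_id": str, "chrom": str}, comment="#",
    )
    if isinstance(df.iloc[0]["tss"], str) or str(df.iloc[0]["gene_id"]).lower() == "gene_id":
        df = df.iloc[1:].reset_index(drop=True)
    return [
        GeneAnnotation(r.gene_id, r.chrom, int(r.tss), int(r.tes)) for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Filtering and harmonization
# ---------------------------------------------------------------------------


def restrict_to_cis_window(table, gene: GeneAnnotation, window_bp: int = 1_000_000):
    """Keep SNPs with ``tss - window <= pos <= tes + window`` (closed bounds).

    Works on any object with ``records`` and a ``subset``/``subset_snps``
    method (summary tables and reference panels).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    lo, hi = gene.tss - window_bp, gene.tes + window_bp
    idx = [
        i
        for i, r in enumerate(table.records)
        if r.chrom == gene.chrom and lo <= r.pos <= hi
    ]
    subset = getattr(table, "subset", None) or table.subset_snps
    return subset(idx)


def hwe_pvalues(panel: ReferencePanel) -> np.ndarray:
    """Hardy-Weinberg chi-square (1 df) p-value per SNP from hard calls."""
    from scipy import stats

    g = np.rint(panel.genotypes)
    pvals = np.empty(panel.n_snps)
    for j in range(panel.n_snps):
        col = g[:, j]
        col = col[~np.isnan(col)]
        n = col.size
        obs = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()], dtype=float)
        q = (obs[1] + 2 * obs[2]) / (2 * n)
        exp = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
        if np.any(exp == 0):
            pvals[j] = 1.0
            continue
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        pvals[j] = stats.chi2.sf(chi2, df=1)
    return pvals


def filter_snps(
    table: EqtlSummaryTable,
    panel: ReferencePanel,
    hapmap3_ids: frozenset = frozenset(),
    maf_min: float = 0.01,
    hwe_min: float = 0.0,
) -> EqtlSummaryTable:
    """Apply the standard SNP quality filters to a summary table.

    Removes SNPs that are (a) below the panel MAF threshold (``maf <
    maf_min`` removed; the boundary value is kept), (b) not biallelic
    single-nucleotide variants, (c) strand-ambiguous (A/T or C/G),
    (d) absent from ``hapmap3_ids`` when that set is non-empty, or
    (e) failing the panel Hardy-Weinberg test at ``p <= hwe_min`` when
    ``hwe_min > 0`` (e.g. 1e-6).  Original order is preserved.  Idempotent.
    """
    panel_maf = dict(zip(panel.snp_ids, panel.maf()))
    panel_hwe = (
        dict(zip(panel.snp_ids, hwe_pvalues(panel))) if hwe_min > 0 else {}
    )
    keep = []
    for i, rec in enumerate(table.records):
        if not rec.is_biallelic_snv or rec.is_ambiguous:
            continue
        if hapmap3_ids and rec.snp_id not in hapmap3_ids:
            continue
        maf = panel_maf.get(rec.snp_id, rec.maf)
        if maf is not None and maf < maf_min:
            continue
        if hwe_min > 0 and panel_hwe.get(rec.snp_id, 1.0) <= hwe_min:
            continue
        keep.append(i)
    return table.subset(keep)


def _match_alleles(s_ref: str, s_alt: str, p_ref: str, p_alt: str):
    """Classify a summary/panel allele pair: +1 same, -1 swapped, None mismatch.

    Non-ambiguous strand flips (complemented alleles) are resolved; anything
    else is dropped.
    """
    s_ref, s_alt = s_ref.upper(), s_alt.upper()
    if (s_ref, s_alt) == (p_ref, p_alt):
        return 1
    if (s_ref, s_alt) == (p_alt, p_ref):
        return -1
    if s_ref in COMPLEMENT and s_alt in COMPLEMENT:
        c_ref, c_alt = COMPLEMENT[s_ref], COMPLEMENT[s_alt]
        if (c_ref, c_alt) == (p_ref, p_alt):
            return 1
        if (c_ref, c_alt) == (p_alt, p_ref):
            return -1
    return None


def harmonize_alleles(table, panel: ReferencePanel):
    """Align a summary table's SNPs and z-score signs to the panel.

    Returns a table of the same type containing only SNPs present in both
    sources, ordered as in the panel, with z flipped wherever the summary's
    counted allele is the panel's other allele.  Unresolvable allele pairs
    (including indels/multi-base records) are dropped and counted in the log.
    """
    by_id = {r.snp_id: i for i, r in enumerate(table.records)}
    keep, signs = [], []
    n_flip = n_drop = 0
    for rec in panel.records:
        i = by_id.get(rec.snp_id)
        if i is None:
            continue
        s = table.records[i]
        m = _match_alleles(s.ref_allele, s.alt_allele, rec.ref_allele, rec.alt_allele)
        if m is None:
            n_drop += 1
            continue
        if m == -1:
            n_flip += 1
        keep.append(i)
        signs.append(m)
    logger.info("harmonize_alleles: kept %d SNPs, flipped %d, dropped %d", len(keep), n_flip, n_drop)
    out = table.subset(keep)
    out.z = out.z * np.asarray(signs, dtype=float)
    # adopt the panel's allele labels so a second pass is the identity
    panel_by_id = {r.snp_id: r for r in panel.records}
    out.records = [
        replace(panel_by_id[r.snp_id], cm=r.cm if r.cm is not None else panel_by_id[r.snp_id].cm)
        for r in out.records
    ]
    return out


def align_panel(panel: ReferencePanel, snp_ids: Sequence[str]) -> ReferencePanel:
    """Subset the panel to ``snp_ids`` preserving the given order."""
    pos = {sid: i for i, sid in enumerate(panel.snp_ids)}
    try:
        idx = [pos[s] for s in snp_ids]
    except KeyError as e:
        raise KeyError(f"SNP {e.args[0]!r} not present in panel") from None
    return panel.subset_snps(idx)
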